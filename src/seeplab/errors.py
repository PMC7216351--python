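"""Exception hierarchy shared across the package."""


class SeeplabError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SeeplabError, ValueError):
    """A circuit or sample parameter violates its physical constraints."""


class RangeError(SeeplabError, ValueError):
    """A requested operating point lies outside the platform's range."""


class CoverageError(SeeplabError, ValueError):
    """A frequency grid does not cover the region an operation needs."""


class EmptyInputError(SeeplabError, ValueError):
    """An operation received an empty trace or table."""


class SamplingRateError(SeeplabError, ValueError):
    """The requested sampling rate undersamples the signal content."""


class UndefinedCorrelationError(SeeplabError, ValueError):
    """Correlation is undefined (zero variance or too few points)."""


class UndefinedMetricError(SeeplabError, ValueError):
    """A signal metric is undefined (e.g. zero-power reference signal)."""


class SpectrumParseError(SeeplabError, ValueError):
    """A spectrum/trace file is malformed; the message names the line."""


class SchemaError(SeeplabError, ValueError):
    """A record does not match the schema expected for its platform."""


class InputError(SeeplabError, ValueError):
    """Generic invalid input (wrong sizes, counts or spans)."""
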