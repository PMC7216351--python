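import dataclasses

import numpy as np
import pytest

import seeplab as sl


@pytest.fixture(scope="session")
def wet_params() -> sl.InterfaceParams:
    """The documented default wet (gel) interface."""
    return sl.DEFAULT_WET


@pytest.fixture(scope="session")
def textile_params() -> sl.InterfaceParams:
    return sl.InterfaceParams(
        kind="textile",
        E_hc=20.0, C_d=100.0, R_d=200.0,
        E_sc=6.0, C_e=0.02, R_e=1000.0,
        E_p=2.0, C_p=0.05, R_p=600.0,
        R_a=40.0, C_t=40.0, R_c=4000.0,
    )


@pytest.fixture(scope="session")
def catalog() -> list[sl.ElectrodeSample]:
    return sl.sample_catalog(0)


@pytest.fixture(scope="session")
def quiet_sample(catalog) -> sl.ElectrodeSample:
    """First catalog sample with every noise channel disabled."""
    return dataclasses.replace(catalog[0], noise=sl.NoiseSpec.off())


@pytest.fixture(scope="session")
def coarse_levels() -> list[float]:
    return [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]


def random_interface(rng: np.random.Generator, kind: str) -> sl.InterfaceParams:
    """Log-uniform random interface over wide but physical ranges."""

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    common = dict(
        E_hc=lu(1, 50), C_d=lu(1, 300), R_d=lu(10, 5000),
        E_sc=lu(1, 20), C_e=lu(0.005, 5), R_e=lu(100, 50000),
        E_p=lu(0.5, 10), C_p=lu(0.01, 5), R_p=lu(100, 20000),
        R_a=lu(5, 500),
    )
    if kind == "wet":
        return sl.InterfaceParams(kind="wet", R_s=lu(5, 500), **common)
    return sl.InterfaceParams(
        kind="textile", C_t=lu(1, 200), R_c=lu(100, 50000),
        moisture=lu(0.2, 5.0), **common,
    )
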