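# Methods

This note documents the models behind `seeplab`: what is simulated, which
parameters matter, the numerical choices, and what the synthetic data can
and cannot tell you about real electrodes.

## The interface circuit

One electrode's skin interface is a lumped resistor–capacitor one-port
with DC offset sources:

```
wet:      Z(f) = (R_d ∥ C_d) + R_s + [(R_e ∥ C_e) ∥ (R_p ∥ C_p)] + R_a
textile:  Z(f) = (R_c ∥ C_t/moisture) + (R_d ∥ C_d)
               + [(R_e ∥ C_e) ∥ (R_p ∥ C_p)] + R_a
```

with `R ∥ C = R / (1 + j·2πf·R·C)`.  The double layer (`R_d`, `C_d`)
models the electrode–electrolyte boundary; the epidermis (`R_e`, `C_e`)
is shunted by the sweat-gland path (`R_p`, `C_p`); the dermis is the pure
resistance `R_a`.  Wet electrodes add the gel resistance `R_s`.  Dry
fabric adds a coupling capacitance `C_t` — scaled by a dimensionless
`moisture` index, since sweat increases capacitive coupling — in parallel
with an ohmic contact resistance `R_c` through the fibres that actually
touch the skin.  The ohmic branch is a modelling necessity as much as a
physical one: a purely capacitive fabric contact would block DC, whereas
measured static (near-DC) impedance of textile electrodes is finite.

Units are Ω, µF, mV, Hz and degrees throughout.  Offset potentials
`E_hc`, `E_sc`, `E_p` do not enter the impedance; their per-electrode sum
sets the pair polarization voltage `PVEP = |ΣE₁ − ΣE₂|`.

Because the network contains only resistors and capacitors, its
driving-point impedance is passive (`Re Z ≥ 0`), its phase lies in
[−90°, 0°], and `|Z(f)|` is non-increasing in frequency.  The test suite
checks these properties on randomized parameter draws, and checks the
closed-form evaluation against an independent admittance-based oracle to
better than 1e−9 relative error.

A measurement stack is two interfaces in series with a tissue/electrolyte
resistance (`R_tissue`, default 150 Ω, the usual magnitude quoted for the
inter-electrode tissue path) and, for signal transfer, a resistive
amplifier input impedance `Z_in`, giving `H(f) = Z_in/(Z_in + Z_pair)`
with `|H| ≤ 1`; `Z_in = None` models an ideal unbounded input.

## Pressure coupling

Contact force `F` changes the electrode–membrane contact, not the
membrane or electrolyte, so only contact elements respond.  With the
saturating drive `s(F) = F/(F + F_half)`:

* contact resistances (`R_d`, plus `R_c` or `R_s`) scale by
  `1/(1 + κ_R·s)`;
* contact capacitances (`C_d`, `C_t`) scale by `1 + κ_C·s`;
* offset potentials scale by `1 − γ_pv·s`.

Defaults: `κ_R = 2.0`, `κ_C = 1.0`, `F_half = 0.5 N`, `γ_pv = 0.2`.  A
saturating monotone law is the simplest form consistent with the two
robust observations on physical platforms: impedance falls with pressure
(strongly at low frequency) and polarization voltage falls modestly.
Catalog draws keep `κ_R ≤ 2·κ_C`; under that constraint each block's
real part and (negative) imaginary part shrink with force at every
frequency, so `|Z(f)|` is *provably* strictly decreasing in force — the
noise-free monotone-trend property the tests assert.

The pair's polarization voltage needs a baseline asymmetry: two
identical electrodes would give `PVEP ≡ 0` at every force.  The fixed
(lower/right) electrode therefore keeps a constant 0.6 share of the base
offset potentials, making the pair mismatch `ΣE·(0.4 − γ_pv·s)` —
positive and strictly decreasing over the catalog parameter ranges.

## The synthetic sessions

A session sweeps the upper (left) electrode over force set points
(default: ten levels uniform in (0, 3] N, within the 0–6 N range of the
two 0–600 cN sensors) while the lower electrode sits at a fixed 123 cN
seat.  Per level it records:

* the pair AC spectrum on the linear band grid (0.1–100 Hz, 0.1 Hz
  steps) and the swept electrode's spectrum on a logarithmic fitting
  grid (0.1–200 Hz, ~50 points/decade);
* a static impedance trace, read at 0.1 Hz (the grid minimum — reading
  slightly off DC keeps the static phase channel informative; exact DC is
  used only for the leakage-current rule);
* a polarization-voltage trace and both contact-pressure traces.

Noise is uniform within the instrument half-ranges observed on the
physical platforms — ±0.14 Ω impedance, 1.85° phase, ±0.65 mV
polarization voltage, ±1.8 cN pressure (drawn per sample from
1.1–5.3 cN) — because tolerances, not distributions, are what such
instruments report.  The measured-signal channel adds Gaussian noise of
RMS `sigma_sig` (default 0.02 mV).  Noisy phases are clamped to
[−90°, 0°], an instrument-style saturation that keeps every written
spectrum valid under the reader's physical-bounds check.

One additional noise channel is structural: `sigma_skin` (default 0.01)
is a fractional jitter applied per force level to the skin-side elements
of both electrodes, modelling membrane/electrolyte state changes between
re-seatings.  It is what shapes the band-resolved correlation structure:
below ~10 Hz the contact elements dominate the spectrum, so the force
sweep drives the band features almost deterministically and their
correlation with the measured force is strong and negative; above 10 Hz
the fabric contact is capacitively shorted, the force signal shrinks
toward the jitter floor, and the correlation magnitude falls off band by
band.  The default of 0.01 was fixed by a design-stage sweep as the value
whose cross-sample correlation profile best matches the shape observed on
physical platforms (low bands ≈ −0.87, monotone decline above 10 Hz);
with all noise off the sessions are exact circuit evaluations.

Relative movement is a triangular constant-speed profile (ranges
0–40 mm/s and 0–100 mm); it multiplies impedance by
`1 + depth·|v(t)|` and adds `depth·|v(t)|` mV to the polarization
voltage, so motion artifacts scale linearly with speed.

Source signals are a sine (0.1–200 Hz generator band) or a periodic
sum-of-Gaussians P-QRS-T template with the R peak pinned to the requested
amplitude; both are deterministic.  The measured signal is the source
multiplied in the frequency domain by `H(f)` of the stack at the first
force level, plus the Gaussian signal noise.

Everything is a pure function of (arguments, seed), via a single
`numpy` generator consumed in fixed order.

## Feature schema and evaluation

Band features sum absolute sampled readings over the eleven bands 0–1,
1–2, 2–3, 3–4, 4–5, 5–10, 10–20, 20–30, 30–40, 40–50, 50–100 Hz.  Sums
are over discrete grid points of the fixed default grid — they are what a
workstation reports — with half-open `[lo, hi)` edges (shared printed
endpoints force a convention) and the last band closed at 100 Hz.  Static
features are trace means; the polarization feature is the mean absolute
trace value.  The 14 electrochemical characteristics are static
impedance, static phase, the 11 magnitude bands and the polarization
voltage; contact pressure contributes USECP, LSECP, SECP_D = USECP −
LSECP and SECP_S = USECP + LSECP.

Method 1 correlates each electrochemical characteristic with each
pressure characteristic per sample across force levels (Pearson, via
`scipy.stats.pearsonr`), then reports the cross-sample mean, standard
deviation and variance (both dispersion readings are emitted so either
convention can be compared).  Significance uses the two-sided t-test on
the mean coefficient at α = 0.01 with `n_levels − 2` degrees of freedom
(critical |r| = 0.7646 at ten levels).  Zero-variance characteristics
are reported as missing, never coerced to zero, and are excluded from
flags.  Method 2 is the same machinery conditioned on movement features.

The conduction-loss report defines its metrics explicitly (the concept
names a comparison, not a formula): lag from the cross-correlation peak;
RMSE after alignment; peak-to-peak attenuation `1 − p2p(out)/p2p(in)`;
per-band power loss `1 − P_band(out)/P_band(in)` clipped at zero (NaN
where the source band is empty); and an SNR difference
`10·log₁₀(1 + P_resid/P_coherent)` after optimal scaling — exactly zero
when the output is a scaled copy of the input, positive as soon as
incoherent noise appears.

The compliance checker applies the disposable-ECG rules: ensemble mean
|Z(10 Hz)| ≤ 2 kΩ over 12 pairs, every pair ≤ 3 kΩ, and test current
≤ 100 µA peak-to-peak.  It takes spectra only; the current rule uses each
spectrum's lowest-frequency magnitude as the DC-offset-impedance proxy.

## Fitting

Over the measurement band the circuit reduces to a series resistance
plus parallel-RC blocks (two parallel RC branches in parallel are exactly
one RC block):

* wet: `R_series = R_s + R_a` plus blocks (`R_d`, `C_d`) and
  (`R_e ∥ R_p`, `C_e + C_p`);
* textile: `R_series = R_a` plus three blocks (contact, double layer,
  epidermis).

Only these combinations are identifiable from AC data: lumped sums are
reported as sums and never split, and offset potentials are excluded.
Fitted blocks are labelled by descending time constant, which maps onto
the named elements at catalog scales.  The textile epidermis block's
corner usually lies far above the band — its capacitance is then weakly
determined — but keeping the block keeps the model exact rather than
truncated (a two-block textile fit leaves a systematic ~0.5% residual
that biases the other blocks by several percent).

The cost is the complex residual weighted by `1/|Z|`, stacked as real
and imaginary parts, minimized by Levenberg–Marquardt (`lmfit`) over
log₁₀-transformed parameters (positivity by construction), with five
seeded multi-starts; the best residual wins, ties broken by the smaller
parameter norm.  Non-convergence is reported in the result, never
raised.

The coupling-law fit runs a per-level spectrum fit (warm-started from
the previous level), then fits `R(F) = R₀/(1 + κ_R·s)` and
`C(F) = C₀·(1 + κ_C·s)` jointly in log space with shared `F_half`
(`scipy.optimize.least_squares`, bounded), and recovers `γ_pv` from a
linear fit of the polarization voltage against `s` using the session's
fixed lower-electrode potential share.  On noise-free sweeps all four
coefficients come back within 5%; at default instrument noise the
double-layer elements stay within 15% (seeded test).

## Problem sizes

Default analyses run at the platform's own scale — 10 samples × 10 force
levels, 1000-point band grids, 167-point fitting grids, 10 s signals at
500 Hz — chosen to mirror the physical workflow; the whole pipeline and
test suite run in well under a minute on one core.

## Limitations

* Lumped RC only: no constant-phase elements, Warburg diffusion,
  temperature or electrode-area effects; real electrode spectra often
  need a CPE where this model uses an ideal capacitor.
* The pressure law is a phenomenological monotone saturation; real
  fabric contacts show hysteresis and creep that are not modelled.
* Noise is independent per reading; real workstation noise is
  correlated across frequency, and drift of the half-cell potentials is
  not simulated (potentials are constants plus trace noise).
* The sample catalog is a random draw from plausible ranges, not a
  characterization of any physical fabric; sample names are labels only.
* Passing the qualitative correlation tests shows the generative
  encoding is self-consistent, not that a particular real fabric would
  show the same coefficients.
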