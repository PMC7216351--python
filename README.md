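# seeplab

Simulation and evaluation of the **skin–electrode electrochemical
interface** (SEEI) for textile (dry) and wet biopotential electrodes.

Textile electrodes pick up ECG/EEG/EMG signals without gel, so their
contact with the skin is capacitive, pressure-dependent and noisy, and
there is no standard human-independent way to characterize them.
Physical evaluation platforms solve this by pressing electrode pairs
against a *simulated skin model* — an electrolyte-filled vessel sealed
with hydrophilic membranes — and measuring static impedance, AC impedance
spectra, polarization voltage, contact pressure, relative movement and,
on the active platform, the conduction loss of an injected source signal.

`seeplab` is a computational twin of such platforms, for people who
develop dry-electrode instrumentation or analysis pipelines and need
reproducible, parameterized measurement data:

* **`seeplab.circuit`** — closed-form equivalent circuits.  One interface
  is `(R_d ∥ C_d) + [(R_e ∥ C_e) ∥ (R_p ∥ C_p)] + R_a`, plus a gel series
  resistance `R_s` (wet) or a fabric contact `R_c ∥ C_t/moisture`
  (textile); DC offset potentials `E_hc + E_sc + E_p` set the pair
  polarization voltage `PVEP = |ΣE₁ − ΣE₂|`.  Pair impedance, amplifier
  transfer `H(f) = Z_in/(Z_in + Z_pair)` and DC leakage current follow.
* **`seeplab.platforms`** — generative measurement sessions: a 10-sample
  textile catalog, contact-force modulation of the contact elements via
  the saturating law `s(F) = F/(F + F_half)`, instrument noise at the
  platform tolerances (±0.14 Ω, 1.85°, ±0.65 mV, ±1.8 cN), triangular
  relative-motion artifacts, and sine/synthetic-ECG source signals.
* **`seeplab.features`** — the platform's feature schema: 11 AC band
  features (ACI_1..ACI_11 over 0–1, 1–2, …, 50–100 Hz), static
  impedance/phase, polarization voltage, the four contact-pressure
  features (USECP, LSECP, their difference and sum) and movement features;
  9-parameter (passive) and 11-parameter (active) session reports.
* **`seeplab.evaluate`** — the three evaluation methods (feature–pressure
  correlation with t-test significance, feature–movement correlation,
  conduction-loss metrics between source and measured signal) and the
  YY/T 0196-2005 disposable-ECG compliance rules (≤ 2 kΩ ensemble mean
  and ≤ 3 kΩ per pair at 10 Hz, ≤ 100 µA test current).
* **`seeplab.fitting`** — complex nonlinear least-squares recovery of the
  identifiable circuit parameters from spectra, and of the
  pressure-coupling coefficients from force sweeps.
* **`seeplab.io` / `seeplab` CLI** — CSV/JSON round-trip formats, a
  validated run configuration and a `simulate → features → evaluate`
  pipeline with a reproducibility manifest.

## Worked example

```python
import seeplab as sl

# a pair of default wet electrodes over 150 ohm of simulated tissue
stack = sl.PairStack(sl.DEFAULT_WET, sl.DEFAULT_WET, R_tissue=150.0)
print(sl.pair_impedance(stack, 0.0).magnitude)   # 1156.6666666666665
print(sl.pair_impedance(stack, 10.0).magnitude)  # 1140.376714789968
print(sl.dc_leakage_current(stack, 100.0))       # 86.45533141210376

# a full passive-platform force sweep for one textile sample
sample = sl.sample_catalog(seed=1)[0]            # "HTL-1"
session = sl.simulate_peep_session(sample, seed=1)
table = sl.feature_table(session)
print(table[["pressure_n", "ACI_3", "PVEP"]].round(2).head(3))
#    pressure_n     ACI_3  PVEP
# 0         0.3  26508.39  6.87
# 1         0.6  25735.51  6.26
# 2         0.9  25332.57  5.81
```

The pair of identical gel electrodes measures 1156.67 Ω at DC (the
capacitors are open, so the value is the plain resistive sum) and
slightly less at 10 Hz; a 100 mV drive pushes 86.5 µA through it, inside
the 100 µA disposable-electrode limit.  The feature table has one row per
force level; `ACI_3` (the 2–3 Hz band sum) falls as the contact force
rises while the fixed-seat pressure stays put, which is exactly the
correlation structure `sl.method1_correlate(table_of_all_samples)`
quantifies.

Command line:

```sh
seeplab simulate --platform PEEP --seed 1 --outdir runs/demo
seeplab features --sessions-dir runs/demo/sessions --out runs/demo/features.csv
seeplab evaluate --features-csv runs/demo/features.csv --out runs/demo/corr.csv
seeplab check-yyt --seed 1 --out runs/demo/compliance.json
```

## Documentation

`docs/methods.md` describes the circuit model, the generative session
model and its calibration, the numerical choices in the fitting routines,
and the limitations of the synthetic data.
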