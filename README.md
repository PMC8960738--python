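# pigatria

Ionically detailed electrophysiology of **pig atrial tissue**: a 12-current
single-cell model, a 1D/2D monodomain tissue solver, the standard cell-level
experimental protocols (voltage clamp, pacing restitution, S1–S2 refractory
measurement), and an analysis toolbox for reentrant spiral waves.

The pig atrium is a workhorse preparation for preclinical atrial-fibrillation
research, but most in-silico work has had to borrow ionic models from other
species. This package implements a porcine-specific atrial cardiomyocyte
model at body temperature and the tissue-level machinery needed to study
propagation, reentry and alternans alongside such experiments.

## The model

The membrane follows the standard Hodgkin–Huxley-type formulation

```
dV/dt = −(I_ion + I_stim)/C_m + D ∇²V        (D = 0 for an isolated cell)
```

with

```
I_ion = I_Na + I_K1 + I_ClCa + I_Kur + I_Kr + I_Ks + I_CaL
      + I_p,Ca + I_NaK + I_NaCa + I_b,Na + I_b,Ca
```

Gating kinetics derive from the classic human atrial and guinea-pig
ventricular formulations with porcine adjustments: a stronger, slower fast
Na⁺ current (g_Na = 13.99 nS/pF, τ_m ×1.7, τ_h and τ_j ×2); an
inward rectifier with its reversal offset by −5 mV (zero crossing at
E_K + 5 ≈ −81.8 mV), 9 % lower conductance and softened rectification; an
ultrarapid K⁺ current with bi-exponential inactivation
(weights a = 0.25, b = 0.75); refitted delayed-rectifier kinetics
(x_r half-rise +4.4451 mV; x_s half-rise p1 = 18.802 mV, slope
p2 = 12.6475 mV); and a reduced L-type Ca²⁺ conductance
(g_CaL = 0.06574 nS/pF).

The distinguishing porcine feature is the transient outward current: it is
entirely a **Ca²⁺-activated Cl⁻ current**,

```
I_to ≡ I_ClCa = g_ClCa · q_Ca · (V − E_Cl),
q_Ca,∞ = 1 − 1/(1 + (F_n / 1.1·10⁻¹⁰)³),  τ_qCa = 2 ms,
```

gated by the myoplasmic Ca²⁺ flux F_n, which couples it tightly to SR
release. I_ClCa produces the early repolarisation notch, has a bell-shaped
IV curve that collapses at strongly positive potentials, and is effectively
shut off at short pacing cycle lengths. The SR Ca²⁺ subsystem (uptake,
release, transfer and leak, with rapid-equilibrium troponin / calmodulin /
calsequestrin buffering) follows the two-compartment scheme of the parent
models.

Tissue is a monodomain sheet on a regular lattice (FTCS, dx = 0.022 cm,
dt = 0.02 ms, D = 0.00126 cm²/ms, no-flux boundaries). The solver ships
with an S1–S2 cross-field protocol for reentry initiation and with spiral
diagnostics: tip tracking (V = −35 mV isoline ∩ dV/dt = 0), tip-trajectory
spectra that preserve the sense of rotation (counter-rotating meander
components appear at signed frequencies), phase-singularity censuses via
±2π phase winding, and APD₉₀ / alternans mapping.

## Worked example

```python
from pigatria import ModelParameters, resting_state, simulate_cell
from pigatria.protocols import extract_ap_features

params = ModelParameters()                  # fitted porcine parameter set
rest = resting_state(params)                # 20 s quiescent equilibration

# three paced beats at 1 Hz (tissue-strength pulse converted through C_m)
trace = simulate_cell(params, rest, duration=3000.0,
                      stim_times=[1.0, 1001.0, 2001.0],
                      stim_amplitude=70.0, stim_duration=1.0)
beat = extract_ap_features(trace.times, trace.V, [1.0, 1001.0, 2001.0])[-1]
print(f"RMP      {beat.RMP:8.1f} mV")
print(f"APA      {beat.APA:8.1f} mV")
print(f"dV/dt_max{beat.dVdt_max:8.1f} mV/ms")
print(f"APD50    {beat.apd[50]:8.1f} ms")
print(f"APD90    {beat.apd[90]:8.1f} ms")
```

prints

```
RMP         -77.9 mV
APA         141.0 mV
dV/dt_max   227.5 mV/ms
APD50        93.5 ms
APD90       187.5 ms
```

i.e. a rate-adapted 1 Hz action potential with a sharp Cl⁻-mediated early
repolarisation phase and ~188 ms duration at 90 % repolarisation.

The same things are available from the shell:

```
pigatria clamp --current I_ClCa --vmin -20 --vmax 60 --out iclca_iv.csv
pigatria restitution --freqs 0.25,0.5,1,2,3,4 --out rest.csv
pigatria erp
pigatria tissue --nx 512 --ny 512 --protocol s1s2 --tmax 40000 --out run.h5
pigatria analyze --run run.h5 --out metrics/
```

`scripts/spiral_run.py` drives the full-resolution (512×512, tens of
seconds) reentry, Cl⁻-block and spiral-breakup experiments; these take hours
on one CPU and are kept out of the test suite.

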