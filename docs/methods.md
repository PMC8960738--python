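# Methods

## Model structure and assumptions

`pigatria` implements a deterministic ordinary-differential-equation model
of a single pig atrial cardiomyocyte and its monodomain extension to 1D
cables and 2D sheets. The cell carries 21 state variables: membrane
potential V; Hodgkin–Huxley gates m, h, j (I_Na), d, f, f_Ca (I_CaL), u_a,
u_if, u_is (I_Kur), x_r (I_Kr), x_s (I_Ks), q_Ca (I_ClCa) and the SR-release
gates u, v, w; and the concentrations [Na]_i, [K]_i, [Ca]_i, [Ca]_up
(uptake compartment) and [Ca]_rel (release compartment). Ca²⁺ buffering by
troponin, calmodulin and calsequestrin uses the rapid-equilibrium
approximation, so buffer occupancies are algebraic functions of the free
concentrations.

The formulation descends from the classic human atrial cell model (which in
turn takes its Ca²⁺ handling from the guinea-pig ventricular dynamic
model), with porcine-specific modifications:

* **I_Na** — conductance 13.99 nS/pF (80 % above the human value), τ_m
  scaled ×1.7, τ_h and τ_j ×2. This slows the upstroke kinetics while
  strengthening the current, matching porcine upstroke-velocity and
  amplitude restitution.
* **I_K1** — numerator (V − E_K − 5): the current reverses at E_K + 5 mV
  (−81.8 mV at [K]o = 5.4, [K]i = 139 mM, 310.15 K); conductance 0.08218
  nS/pF (9 % below human); rectification exp(0.063 (V + 70)) (slope reduced
  10 %, half-rise shifted +10 mV).
* **I_Kur** — bi-exponential inactivation: I_Kur = g_Kur(V) u_a³
  (0.25 u_if + 0.75 u_is)(V − E_K) with g_Kur(V) = g_Kur,amp (0.005 +
  0.05 / (1 + exp(−(V − 15)/13))), g_Kur,amp = 0.45539 nS/pF.
* **I_Kr** — x_r,∞ half-rise at +4.4451 mV, slope 9.3305 mV; the
  rectification denominator uses half-point 79.4825 mV and slope 8.2217 mV,
  so the correction is ≈1 throughout the plateau range and only bites at
  strongly positive potentials.
* **I_Ks** — x_s,∞ = [1 + exp(−(V − p1)/p2)]^(−1/2) with p1 = 18.802 mV,
  p2 = 12.6475 mV; τ_s keeps the parent rate functions centred on p1.
* **I_CaL** — I_CaL = g_CaL d f f_Ca (V − 65), g_CaL = 0.06574 nS/pF;
  f_Ca,∞ = 1/(1 + [Ca]_i/0.00035), τ_fCa = 2 ms.
* **I_ClCa** — the entire transient outward current:
  g_ClCa q_Ca (V − E_Cl) with g_ClCa = 0.15731 nS/pF and E_Cl fixed at
  −40.264 mV (Nernst for 29.26/132 mM Cl⁻ at 310.15 K; intracellular Cl⁻ is
  not a state variable). q_Ca,∞ = 1 − 1/(1 + (F_n/1.1·10⁻¹⁰)³), τ = 2 ms,
  driven by the myoplasmic Ca²⁺ flux
  F_n = 10⁻¹² V_rel I_rel − (5·10⁻¹³/F)(0.5 I_CaL − 0.2 I_NaCa) C_m
  (total-cell currents in pA). Negative F_n (inward-trigger-dominated) is
  clipped to zero inside the cubic Hill curve to keep q_Ca,∞ in [0, 1].
* **SR release inactivation (w gate)** — half-point moved from +40 to
  +80 mV with the slope steepened from 17 to 8.5 mV. The voltage
  inactivation of release is thereby pushed out of the plateau range; the
  bell shape of the I_ClCa IV curve at high positive potentials then arises
  from the vanishing L-type trigger near its 65 mV driving-force null,
  which reproduces the observed IV morphology. (Moving the half-point the
  other way suppresses release at all plateau potentials and kills the
  current — see "resolved ambiguities" below.)

Pumps, exchanger, background currents, SR fluxes, buffers and the
concentration ODEs are carried over verbatim from the parent formulations,
with the fitted maxima I_NaK,max = 0.94935 pA/pF and the exchanger scaling
constant 2304.

## Parameters

All conductances are in nS/pF, currents in pA/pF, concentrations in mM,
voltages in mV, time in ms. `ModelParameters` exposes every constant;
defaults are the fitted porcine set. The ones a user most often touches:

| parameter | default | meaning |
|---|---|---|
| `g_Kr` | 0.0173 | rapid delayed rectifier; ×0.25 induces spiral breakup |
| `g_ClCa` | 0.15731 | Ca-activated Cl⁻ current; ×0.5/×0.1 replays the block experiments |
| `D` | 0.00126 cm²/ms | monodomain diffusion; sets CV ≈ 0.6 m/s |
| `C_m` | 100 pF | used only to convert whole-cell stimuli (7 nA → 70 pA/pF) |
| `d_inf_shift`, `d_tau_shift` | 0, +5 mV | independent half-point shifts of the L-type activation curve / time constant |
| `tau_uis_factor` | 20 | slow-to-fast ratio of the I_Kur inactivation time constants |

Stimulus convention: amplitudes are positive-depolarising pA/pF and enter
the voltage equation additively; the tissue pulse is 7 nA for 4 ms
(70 pA/pF through C_m), cell-level protocols use the same amplitude at the
experimental 1 ms monophasic width (a 4 ms pulse over-drives an isolated
cell, which has no diffusive load; see "stability").

## Numerics

* Forward Euler for V and concentrations at dt = 0.02 ms, matching the
  forward-time centred-space (FTCS) tissue scheme with dx = dy = 0.022 cm
  (stability ratio D·dt/dx² ≈ 0.052, limit 0.25; violating it raises).
  Gates use forward Euler by default; an exponential (Rush–Larsen) update
  is available (`scheme="rush-larsen"`) and guarantees gate bounds for any
  step size.
* Removable singularities in the rate functions (α_m at V = −47.13, τ_d at
  its half-point, τ_w at 7.9 mV, x_r/x_s rates) switch to their analytic
  limits within 10⁻⁶ mV.
* No-flux boundaries via mirrored ghost nodes; the 5-point Laplacian
  conserves the discrete field integral exactly under pure diffusion.
* **Stability envelope.** At dt = 0.02 ms the Euler gate update is stable
  for V ≳ −84 mV and V ≲ +200 mV (outside that range τ_m < dt/2). The
  model's own trajectories stay well inside; strongly hyperpolarising or
  massively supra-threshold stimuli need Rush–Larsen or a smaller dt.
  Non-finite states raise a `FloatingPointError` naming the variable.
* Halving dt changes the 1 Hz APD₉₀ by < 1 ms (tested). Halving dx (with
  dt/4) raises CV by ≈ 4.5 %: the published grid carries a few percent of
  discretisation error, reduced monotonically by refinement. Simulations
  therefore use the published grid, not the continuum limit.
* Measurement conventions: wavefront arrival = upstroke crossing of
  −35 mV; waveback = repolarisation crossing of −40 mV; wavelength =
  (waveback − wavefront time) × CV; APD_X = time above the X %
  repolarisation level with linear interpolation at the crossings; all
  threshold crossings are interpolated between samples.
* Everything is deterministic — identical inputs give bit-identical
  trajectories. There is no randomness anywhere in the model.

## Protocols

* **Voltage clamp**: hold (default −80 mV) for one interpulse interval so
  gates settle, then step; V is clamped while gates and Ca²⁺ evolve. The
  L-type IV protocol pins [Ca]_i at 0.0001 mM, under which the peak
  |I_CaL| is 2.55 pA/pF, inside the measured 3.25 ± 0.75 band.
* **Restitution**: pacing at 0.25–4 Hz, features averaged over the last 10
  captured beats. Late APDs (60–90 %) grow monotonically with cycle
  length; peak I_ClCa and peak F_n collapse at short cycle lengths
  (the Cl⁻ current is effectively shut off by 4 Hz).
* **ERP**: ≥5 conditioning S1 at CL 1000 ms, then bisection of the S1–S2
  coupling interval to 1 ms. Capture requires both an amplitude > 60 mV
  above the takeoff potential and a regenerative upstroke (dV/dt in excess
  of the direct stimulus contribution > 20 mV/ms) — a bare amplitude rule
  misfires on the capacitive deflection when S2 lands on the plateau.
  A cable mode (`mode="cable"`) instead requires propagation to the far
  end; the two agree to a few ms (cell 219.9 ms, cable 213.8 ms).
* **S1–S2 cross field**: S1 line stimulus (5 nodes) on the left edge; S2
  fires over the lower half-plane when the S1 waveback (−40 mV) clears the
  domain midline. Snapshots default to a 10 ms cadence, which is also the
  tip-tracking cadence.

## Spiral analysis

Tips are sub-grid intersections of the V = −35 mV isoline with the zero
contour of the inter-frame voltage difference (marching squares + segment
intersection), linked by nearest-neighbour continuity with a 1 cm/frame
gate. The trajectory spectrum is the DFT of the mean-removed complex path
x + iy, so rotation sense survives as the frequency sign; peaks are refined
by parabolic interpolation, and for counter-rotating dominant components at
f₀, f₁ the meander flower closes after ≈ |f₀ − f₁|/|f₀ + f₁| petals (5 for
the +5.426/−3.548 Hz pattern). Phase singularities are counted as ±2π
windings of θ = atan2(V(t) − V*, V(t−τ) − V*) around lattice plaquettes
(V* = −35 mV, τ = one frame). APD₉₀ mapping samples every 8th node,
excludes sites within 1 cm of a supplied tip path, and flags alternans when
consecutive-beat |ΔAPD₉₀| exceeds 5 ms (the threshold is a package choice;
no standard value exists).

## Synthetic generators

`pigatria.synthetic` produces analytic stand-ins with exact ground truth:
rotating Archimedean-spiral voltage patterns with a pinned core (tip
tracking oracle), phase fields with prescribed singularity counts, two-
phasor hypocycloid trajectories (spectrum/petal oracle), travelling bands
and rectangular AP trains (feature-extraction and alternans oracles).
These validate the *analysis* pipeline with known answers; they do not
reproduce electrotonic coupling, front curvature, meander irregularity or
measurement noise of real optical maps, so passing them certifies the
measurement code, not tissue physiology. The physiology itself is exercised
by the cable and sheet simulations at the published grid.

## Resolved ambiguities (design choices)

Where the printed source material under-determines the model, the package
resolves the ambiguity against the quantitative porcine anchors it is meant
to reproduce (CV ≈ 0.58 m/s, wavelength 8 cm at low rate and 5 cm at a
200 ms cycle length, ERP ≈ 215 ms, clamped |I_CaL| = 3.25 ± 0.75 pA/pF,
bell-shaped I_ClCa IV):

* **L-type activation "+5 mV shift"**: applied to the activation *time
  constant* (τ_d evaluated at V − 5), leaving d∞ at the parent half-point
  of −10 mV. Shifting d∞ itself in either direction breaks several anchors
  at once (half-point −5 mV: wavelength 6.8 cm, ERP 174 ms, |I_CaL| 2.42;
  half-point −15 mV: wavelength 10.4 cm, ERP 230 ms, 2:1 block at CL
  200 ms). Both readings remain available through `d_inf_shift`.
* **Release inactivation "+40 mV, steeper"**: half-point +80 mV, slope
  8.5 mV (see above); the slope factor 2 is a package choice, the shift
  direction is fixed by the IV-curve morphology.
* **Slow I_Kur inactivation**: same steady state as the fast component,
  τ_slow = 20 × τ_fast.
* **Resting state**: source-model initial values advanced 20 s without
  stimulus define the packaged quiescent state used by every protocol. The
  true equilibrium is approached over minutes (slow Na⁺ relaxation): after
  200 s the residual drift of all Ca²⁺ state variables is below 1 % per
  10 s, which is how the quiescence property is verified.
* **ERP stimulus and capture**: see Protocols.

## Known limitations

* With every printed parameter taken verbatim, the simulated CV on the
  published grid is 0.62 m/s, ~7 % above the 0.58 m/s target; the 1 Hz
  wavelength (8.9 cm) inherits this excess — the front-to-back interval
  itself (≈ 143 ms) is within 4 % of the value implied by the published
  wavelength and CV. No printed parameter reading was found that removes
  the excess; it is reported, not tuned away.
* The isolated cell overshoots to ≈ +59 mV (electrotonic loading brings the
  tissue overshoot to ≈ +38 mV). Because the Ca²⁺-flux trigger depends on
  the L-type driving force, SR release — and with it I_ClCa — is much
  weaker in an isolated cell than in propagated beats. Clamp protocols and
  tissue runs show the full-sized current; 0D restitution shows the correct
  trends at reduced amplitude.
* Intracellular concentrations drift slowly during long runs (a property
  inherited from the parent Ca²⁺/Na⁺ formulations); multi-minute
  simulations should be interpreted with that in mind.
* Homogeneous, isotropic monodomain tissue only: no fibre anisotropy,
  heterogeneity, fibrosis or 3D anatomy.
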