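"""Cell-level experimental protocols.

Voltage-clamp IV curves, action-potential feature extraction, pacing
restitution (including the peak I_ClCa / peak Ca2+-flux restitution), and
effective-refractory-period measurement by S1-S2 bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _layout as L
from ._kernel import integrate_cell
from .ionic_model import currents_from_states, simulate_cell
from .parameters import ModelParameters
from .state import CellState, resting_state

__all__ = [
    "ClampProtocol", "APFeatures", "run_voltage_clamp",
    "extract_ap_features", "run_restitution", "measure_erp",
    "CAPTURE_APA_MV",
]

#: a beat counts as captured when its amplitude exceeds this (mV)
CAPTURE_APA_MV = 60.0

#: default cell-level stimulus: the tissue pulse amplitude converted through
#: C_m, at the 1 ms monophasic width used experimentally.  (The 4 ms tissue
#: pulse relies on diffusion to shed charge and over-drives an isolated cell.)
DEFAULT_STIM_AMPLITUDE = 70.0  # pA/pF
DEFAULT_STIM_DURATION = 1.0    # ms


@dataclass
class ClampProtocol:
    """Square-step voltage-clamp protocol.

    The membrane is held at ``holding_potential`` long enough for gates to
    settle, then stepped to each test potential for ``step_duration`` ms
    while the chosen current is recorded.  ``measurement_rule`` is ``"peak"``
    (signed value of largest magnitude) or ``"steady"`` (end of step).
    ``cai_clamp`` optionally pins [Ca2+]_i (mM) during the whole protocol.
    """

    test_potentials: tuple
    holding_potential: float = -80.0
    step_duration: float = 300.0
    interpulse_interval: float = 1000.0
    measured_current: str = "I_CaL"
    measurement_rule: str = "peak"
    cai_clamp: float | None = None

    def __post_init__(self) -> None:
        self.test_potentials = tuple(float(v) for v in self.test_potentials)
        if not self.test_potentials:
            raise ValueError("test_potentials must be non-empty")
        if any(b <= a for a, b in zip(self.test_potentials,
                                      self.test_potentials[1:])):
            raise ValueError("test_potentials must be strictly increasing")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if self.measured_current not in L.CURRENT_NAMES:
            raise KeyError(f"unknown current {self.measured_current!r}; "
                           f"choose one of {L.CURRENT_NAMES}")
        if self.measurement_rule not in ("peak", "steady"):
            raise ValueError("measurement_rule must be 'peak' or 'steady'")


def run_voltage_clamp(protocol: ClampProtocol,
                      params: ModelParameters | None = None,
                      dt: float = 0.02,
                      record_every: float = 0.1) -> pd.DataFrame:
    """Simulated patch-clamp experiment.

    V is clamped (held, then stepped); gates and the Ca2+ subsystem evolve
    freely.  Returns a DataFrame with one row per test potential
    (columns ``V_test``, ``current``) plus the recorded step traces in
    ``df.attrs["traces"]``.
    """
    pr = params or ModelParameters()
    p = pr.pack()
    clamp_cai = int(protocol.cai_clamp is not None)

    hold = resting_state(pr).as_array()
    hold[L.IV, 0] = protocol.holding_potential
    if clamp_cai:
        hold[L.ICAI, 0] = protocol.cai_clamp
    n_hold = int(round(protocol.interpulse_interval / dt))
    no_rec = np.empty((0, L.NVAR))
    integrate_cell(hold, p, dt, np.zeros(n_hold), 0, 1, clamp_cai, 1, 0, no_rec)

    stride = max(int(round(record_every / dt)), 1)
    nstep = int(round(protocol.step_duration / dt))
    nrec = (nstep + stride - 1) // stride

    rows, traces = [], {}
    for v_test in protocol.test_potentials:
        S = hold.copy()
        S[L.IV, 0] = v_test
        rec = np.empty((nrec, L.NVAR))
        nw = integrate_cell(S, p, dt, np.zeros(nstep), 0, 1, clamp_cai, 1,
                            stride, rec)
        cur = currents_from_states(rec[:nw], pr)[protocol.measured_current]
        if protocol.measurement_rule == "peak":
            value = float(cur[np.argmax(np.abs(cur))])
        else:
            value = float(cur[-1])
        rows.append((v_test, value))
        traces[v_test] = cur
    df = pd.DataFrame(rows, columns=["V_test", "current"])
    df.attrs["traces"] = traces
    df.attrs["times"] = np.arange(nrec) * stride * dt
    return df


# --------------------------------------------------------------------------
# AP features
# --------------------------------------------------------------------------

@dataclass
class APFeatures:
    """Features of one evoked beat.

    ``apd`` maps the repolarisation percentage X (10..90) to APD_X, the time
    spent above the X%-repolarisation level (linear interpolation at the
    crossings).  ``captured`` is False when APA fails the capture criterion;
    numeric fields are then NaN.
    """

    stim_time: float
    captured: bool
    RMP: float = float("nan")
    APA: float = float("nan")
    dVdt_max: float = float("nan")
    apd: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"stim_time": self.stim_time, "captured": self.captured,
               "RMP": self.RMP, "APA": self.APA, "dVdt_max": self.dVdt_max}
        row.update({f"APD{x}": self.apd.get(x, float("nan"))
                    for x in sorted(self.apd)})
        return row


def _time_above(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """Total time v >= level, linearly interpolating segment ends."""
    above = v >= level
    if not above.any():
        return 0.0
    total = 0.0
    # segment boundaries
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    for s, e in zip(starts, ends):
        t0 = t[s] if s == 0 else np.interp(
            level, [v[s], v[s - 1]], [t[s], t[s - 1]])
        t1 = t[e - 1] if e == len(v) else np.interp(
            level, [v[e], v[e - 1]], [t[e], t[e - 1]])
        total += t1 - t0
    return float(total)


def extract_ap_features(times: np.ndarray, V: np.ndarray,
                        pacing_times,
                        apd_levels=(10, 20, 30, 40, 50, 60, 70, 80, 90),
                        capture_apa: float = CAPTURE_APA_MV
                        ) -> list[APFeatures]:
    """Per-beat AP features from a voltage trace.

    For each stimulus time the beat window runs to the next stimulus (or the
    end of the trace).  RMP is the pre-stimulus potential, APA the peak
    relative to RMP, dV/dt_max the maximum centred difference on the
    upstroke; a beat with APA below ``capture_apa`` is flagged not captured
    rather than raising.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    pacing_times = sorted(float(s) for s in pacing_times)
    out = []
    for k, s in enumerate(pacing_times):
        end = pacing_times[k + 1] if k + 1 < len(pacing_times) else np.inf
        pre = np.flatnonzero(times < s)
        win = (times >= s) & (times < end)
        if pre.size == 0 or win.sum() < 3:
            out.append(APFeatures(stim_time=s, captured=False))
            continue
        rmp = float(V[pre[-1]])
        tb, vb = times[win], V[win]
        vmax = float(vb.max())
        apa = vmax - rmp
        if apa <= capture_apa:
            out.append(APFeatures(stim_time=s, captured=False, RMP=rmp,
                                  APA=apa))
            continue
        ipk = int(np.argmax(vb))
        dv = np.gradient(vb, tb)
        dvdt_max = float(dv[:ipk + 1].max()) if ipk >= 1 else float("nan")
        apd = {x: _time_above(tb, vb, vmax - x / 100.0 * apa)
               for x in apd_levels}
        out.append(APFeatures(stim_time=s, captured=True, RMP=rmp, APA=apa,
                              dVdt_max=dvdt_max, apd=apd))
    return out


# --------------------------------------------------------------------------
# restitution
# --------------------------------------------------------------------------

def run_restitution(frequencies,
                    params: ModelParameters | None = None,
                    n_beats: int = 12,
                    n_average: int = 10,
                    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE,
                    stim_duration: float = DEFAULT_STIM_DURATION,
                    dt: float = 0.02,
                    record_every: float = 0.5,
                    state: CellState | None = None) -> pd.DataFrame:
    """Pacing restitution at the given frequencies (Hz).

    Each frequency is paced for ``n_beats`` from the quiescent state;
    features (and the per-beat peak I_ClCa and peak Ca2+ flux F_n) are
    averaged over the last ``n_average`` captured beats.  A frequency is
    flagged ``capture_1to1 = False`` when any beat in the averaging window
    fails the capture criterion.
    """
    pr = params or ModelParameters()
    st = state if state is not None else resting_state(pr)
    rows = []
    for f_hz in frequencies:
        cl = 1000.0 / f_hz
        stim_times = [1.0 + k * cl for k in range(n_beats)]
        tr = simulate_cell(pr, st, duration=n_beats * cl + 400.0, dt=dt,
                           stim_times=stim_times,
                           stim_amplitude=stim_amplitude,
                           stim_duration=stim_duration,
                           record_every=record_every)
        feats = extract_ap_features(tr.times, tr.V, stim_times)
        window = feats[-n_average:]
        captured = [f for f in window if f.captured]
        cur = tr.currents()
        peak_icl, peak_fn = [], []
        for f0 in window:
            m = (tr.times >= f0.stim_time) & (tr.times < f0.stim_time + cl)
            peak_icl.append(float(cur["I_ClCa"][m].max()))
            peak_fn.append(float(cur["F_n"][m].max()))
        row = {"frequency_hz": f_hz, "cycle_length_ms": cl,
               "capture_1to1": len(captured) == len(window),
               "n_beats_averaged": len(captured),
               "peak_I_ClCa": float(np.mean(peak_icl)),
               "peak_F_n": float(np.mean(peak_fn))}
        if captured:
            row["RMP"] = float(np.mean([f.RMP for f in captured]))
            row["APA"] = float(np.mean([f.APA for f in captured]))
            row["dVdt_max"] = float(np.mean([f.dVdt_max for f in captured]))
            for x in sorted(captured[0].apd):
                row[f"APD{x}"] = float(np.mean([f.apd[x] for f in captured]))
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# effective refractory period
# --------------------------------------------------------------------------

def _s2_captures(cond_state: np.ndarray, pr: ModelParameters, ci: float,
                 stim_amplitude: float, stim_duration: float,
                 dt: float) -> bool:
    """Does an S2 delivered ``ci`` ms after the last S1 evoke a full AP?

    Capture requires (i) a regenerative upstroke — dV/dt in excess of the
    direct stimulus contribution — and (ii) a full amplitude above the
    takeoff potential, so neither the capacitive stimulus deflection nor a
    graded local response counts.
    """
    tr = simulate_cell(pr, CellState.from_array(cond_state),
                       duration=ci + 400.0, dt=dt,
                       stim_times=[0.0, ci],
                       stim_amplitude=stim_amplitude,
                       stim_duration=stim_duration,
                       record_every=0.1)
    t = tr.times
    dvdt = np.gradient(tr.V, t)
    interior = (t >= ci + 0.3) & (t <= ci + stim_duration - 0.2)
    post = t >= ci + stim_duration + 0.3
    regen = -np.inf
    if interior.any():
        regen = float((dvdt[interior] - stim_amplitude).max())
    if post.any():
        regen = max(regen, float(dvdt[post].max()))
    pre = np.flatnonzero(t < ci)
    takeoff = float(tr.V[pre[-1]]) if pre.size else float(tr.V[0])
    return (regen > 20.0
            and float(tr.V[t >= ci].max()) - takeoff > CAPTURE_APA_MV)


def measure_erp(params: ModelParameters | None = None,
                s1_count: int = 6,
                s1_cl: float = 1000.0,
                stim_amplitude: float = DEFAULT_STIM_AMPLITUDE,
                stim_duration: float = DEFAULT_STIM_DURATION,
                resolution: float = 1.0,
                bracket: tuple[float, float] = (120.0, 450.0),
                dt: float = 0.02,
                mode: str = "cell",
                cable_length_cm: float = 3.0) -> float:
    """Effective refractory period (ms) by S1-S2 bisection.

    After ``s1_count`` conditioning stimuli at cycle length ``s1_cl``, the
    S1-S2 coupling interval is bisected to ``resolution``; the ERP is the
    shortest interval whose S2 still evokes a full AP (APA above the capture
    criterion).  ``mode="cell"`` runs an isolated cell; ``mode="cable"``
    stimulates one end of a cable and requires the S2 response to propagate
    to the far end.
    """
    if s1_count < 5:
        raise ValueError("need at least 5 conditioning stimuli")
    if mode == "cable":
        return _measure_erp_cable(params, s1_count, s1_cl, resolution,
                                  bracket, dt, cable_length_cm)
    if mode != "cell":
        raise ValueError("mode must be 'cell' or 'cable'")
    pr = params or ModelParameters()
    # condition, stopping exactly at the onset of the last S1
    cond = simulate_cell(pr, resting_state(pr),
                         duration=(s1_count - 1) * s1_cl, dt=dt,
                         stim_times=[1.0 + k * s1_cl
                                     for k in range(s1_count - 1)],
                         stim_amplitude=stim_amplitude,
                         stim_duration=stim_duration,
                         record_every=5.0)
    cond_state = cond.states[-1].reshape(L.NVAR, 1).copy()

    lo, hi = bracket
    if _s2_captures(cond_state, pr, lo, stim_amplitude, stim_duration, dt):
        raise ValueError(f"capture already at the bracket floor {lo} ms; "
                         "widen the bracket")
    if not _s2_captures(cond_state, pr, hi, stim_amplitude, stim_duration, dt):
        raise ValueError(f"no capture even at coupling interval {hi} ms")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _s2_captures(cond_state, pr, mid, stim_amplitude,
                        stim_duration, dt):
            hi = mid
        else:
            lo = mid
    return hi


def _measure_erp_cable(params, s1_count, s1_cl, resolution, bracket, dt,
                       length_cm):
    """Cable-mode ERP: capture means a propagated front at the far end."""
    from .tissue import TissueField, StimulusRegion  # local: avoid heavy import

    pr = params or ModelParameters()
    dx = 0.022
    nx = int(round(length_cm / dx)) + 1
    field = TissueField(nx, 1, pr, dx=dx, dt=dt)
    mask = field.column_mask(0, 5)
    cond = [StimulusRegion(mask, 70.0, 1.0 + k * s1_cl, 4.0)
            for k in range(s1_count - 1)]
    field.run((s1_count - 1) * s1_cl + 1.0, cond)
    S_cond = field.S.copy()
    probe = nx - 10

    def propagates(ci):
        g = TissueField(nx, 1, pr, dx=dx, dt=dt)
        g.S = S_cond.copy()
        st = [StimulusRegion(mask, 70.0, 0.0, 4.0),
              StimulusRegion(mask, 70.0, ci, 4.0)]
        t, pv, _, _ = g.run(ci + 120.0, st, probes=[probe], probe_every=0.1)
        v = pv[:, 0]
        ups = np.flatnonzero((v[:-1] < -35.0) & (v[1:] >= -35.0))
        return any(t[u] > ci + 2.0 for u in ups)

    lo, hi = bracket
    if propagates(lo):
        raise ValueError(f"capture already at the bracket floor {lo} ms")
    if not propagates(hi):
        raise ValueError(f"no capture even at coupling interval {hi} ms")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    return hi
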