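"""Monodomain tissue solver: 1D cables and 2D sheets.

The membrane model is coupled by a diffusion term,
``dV/dt = -(I_ion + I_stim)/C_m + D * laplacian(V)``, integrated with the
explicit forward-time centred-space (FTCS) scheme on a regular lattice with
no-flux (mirrored ghost node) boundaries.  Defaults: dx = dy = 0.022 cm,
dt = 0.02 ms, D = 0.00126 cm^2/ms, which keeps the stability ratio
D*dt/dx^2 ~ 0.05, far below the 2D limit of 0.25.

Wave measurements follow the conventions used throughout the package:
wavefront arrival is the upstroke crossing of -35 mV and the waveback is the
repolarisation crossing of -40 mV, so the wavelength of a paced wave is
``WL = (t_back(-40 mV) - t_front) * CV``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _layout as L
from ._kernel import step_cells
from .parameters import ModelParameters
from .state import CellState, resting_state

FRONT_THRESHOLD_MV = -35.0
BACK_THRESHOLD_MV = -40.0

__all__ = [
    "TissueField", "StimulusRegion", "laplacian", "step_tissue",
    "run_cable", "measure_cv", "measure_wavelength", "s1s2_crossfield",
    "paced_wavelength", "FRONT_THRESHOLD_MV", "BACK_THRESHOLD_MV",
]


@dataclass
class StimulusRegion:
    """Rectangular pulse applied to a set of lattice sites.

    ``mask`` is a boolean array over the flattened lattice; ``amplitude`` is
    in pA/pF (positive = depolarising); ``start``/``duration`` in ms.
    """

    mask: np.ndarray
    amplitude: float
    start: float
    duration: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if not self.mask.any():
            raise ValueError("stimulus mask must be non-empty")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


class TissueField:
    """2D (or 1D when ny == 1) lattice of cells sharing one parameter set."""

    def __init__(self, nx: int, ny: int = 1,
                 params: ModelParameters | None = None,
                 dx: float = 0.022, dt: float = 0.02,
                 initial_state: CellState | None = None,
                 scheme: str = "euler"):
        self.nx = int(nx)
        self.ny = int(ny)
        self.params = params or ModelParameters()
        self.dx = float(dx)
        self.dt = float(dt)
        self.time = 0.0
        self.rush_larsen = {"euler": 0, "rush-larsen": 1}[scheme]
        self._p = self.params.pack()
        ratio = self.params.D * self.dt / self.dx ** 2
        if ratio > 0.25:
            raise ValueError(
                f"FTCS stability violated: D*dt/dx^2 = {ratio:.3f} > 0.25")
        init = initial_state if initial_state is not None \
            else resting_state(self.params)
        n = self.nx * self.ny
        self.S = np.repeat(init.as_array(), n, axis=1)

    # -- geometry helpers -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def V(self) -> np.ndarray:
        """Membrane potential as an (ny, nx) array (view)."""
        return self.S[L.IV].reshape(self.ny, self.nx)

    def x_coords(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    def column_mask(self, i0: int, i1: int) -> np.ndarray:
        m = np.zeros((self.ny, self.nx), dtype=bool)
        m[:, i0:i1] = True
        return m.ravel()

    def half_plane_mask(self, rows_below: int) -> np.ndarray:
        m = np.zeros((self.ny, self.nx), dtype=bool)
        m[:rows_below, :] = True
        return m.ravel()

    # -- stepping -------------------------------------------------------------
    def step(self, stimuli: list[StimulusRegion] | None = None) -> None:
        step_tissue(self, stimuli or [], self.dt)

    def run(self, duration: float,
            stimuli: list[StimulusRegion] | None = None,
            probes: np.ndarray | list | None = None,
            probe_every: float = 0.1,
            snapshot_every: float | None = None,
            check_every: float = 5.0):
        """Advance ``duration`` ms.

        Returns ``(probe_times, probe_V, snapshot_times, snapshots)``:
        voltages at flat probe indices every ``probe_every`` ms and, when
        ``snapshot_every`` is set, copies of the V field at that cadence.
        """
        stimuli = stimuli or []
        nstep = int(round(duration / self.dt))
        probe_idx = (np.asarray(probes, dtype=int)
                     if probes is not None else None)
        pstride = max(int(round(probe_every / self.dt)), 1)
        sstride = (int(round(snapshot_every / self.dt))
                   if snapshot_every else 0)
        cstride = max(int(round(check_every / self.dt)), 1)
        ptimes, pv, stimes, snaps = [], [], [], []
        for k in range(nstep):
            if probe_idx is not None and k % pstride == 0:
                ptimes.append(self.time)
                pv.append(self.S[L.IV, probe_idx].copy())
            if sstride and k % sstride == 0:
                stimes.append(self.time)
                snaps.append(self.V.copy())
            self.step(stimuli)
            if k % cstride == 0 and not np.isfinite(self.S[L.IV]).all():
                raise FloatingPointError(
                    f"tissue simulation diverged at t = {self.time:.2f} ms")
        return (np.asarray(ptimes), np.asarray(pv),
                np.asarray(stimes), np.asarray(snaps))


def laplacian(V: np.ndarray) -> np.ndarray:
    """5-point Laplacian (units of 1/dx^2) with no-flux boundaries
    implemented by mirrored ghost nodes."""
    Vp = np.pad(V, 1, mode="edge")
    return (Vp[:-2, 1:-1] + Vp[2:, 1:-1] + Vp[1:-1, :-2] + Vp[1:-1, 2:]
            - 4.0 * V)


def step_tissue(field: TissueField, stimuli: list[StimulusRegion],
                dt: float) -> TissueField:
    """One FTCS step: diffusion on V plus the local ionic update (in place)."""
    coeff = field.params.D / field.dx ** 2
    extra = (coeff * laplacian(field.V)).ravel()
    for stim in stimuli:
        if stim.active(field.time):
            extra[stim.mask] += stim.amplitude
    step_cells(field.S, extra, dt, field._p, field.rush_larsen, 0, 0, 1)
    field.time += dt
    return field


# --------------------------------------------------------------------------
# wave measurements
# --------------------------------------------------------------------------

def _crossing_time(t: np.ndarray, v: np.ndarray, level: float,
                   rising: bool, t_after: float = -np.inf) -> float:
    """First linear-interpolated crossing of ``level`` after ``t_after``."""
    v = np.asarray(v, dtype=float)
    if rising:
        hits = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    else:
        hits = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
    for k in hits:
        tc = t[k] + (level - v[k]) / (v[k + 1] - v[k]) * (t[k + 1] - t[k])
        if tc >= t_after:
            return tc
    raise ValueError(f"no {'upstroke' if rising else 'repolarisation'} "
                     f"crossing of {level} mV found")


def measure_cv(probe_times: np.ndarray, probe_V: np.ndarray,
               probe_positions_cm: tuple[float, float],
               threshold: float = FRONT_THRESHOLD_MV,
               t_after: float = -np.inf) -> float:
    """Conduction velocity (cm/s) from front arrival at two probes.

    ``probe_V`` has one column per probe; arrival is the upstroke crossing
    of ``threshold``.
    """
    t0 = _crossing_time(probe_times, probe_V[:, 0], threshold, True, t_after)
    t1 = _crossing_time(probe_times, probe_V[:, 1], threshold, True, t_after)
    if t1 == t0:
        raise ValueError("wavefront reached both probes simultaneously")
    dist = abs(probe_positions_cm[1] - probe_positions_cm[0])
    return dist / abs(t1 - t0) * 1000.0


def measure_wavelength(probe_times: np.ndarray, probe_V_single: np.ndarray,
                       cv_cm_per_s: float,
                       front_threshold: float = FRONT_THRESHOLD_MV,
                       back_threshold: float = BACK_THRESHOLD_MV,
                       t_after: float = -np.inf) -> float:
    """Wavelength (cm): time between wavefront arrival (upstroke through
    -35 mV) and waveback repolarisation (through -40 mV) at one probe,
    multiplied by the conduction velocity."""
    t_front = _crossing_time(probe_times, probe_V_single, front_threshold,
                             True, t_after)
    t_back = _crossing_time(probe_times, probe_V_single, back_threshold,
                            False, t_front)
    return (t_back - t_front) / 1000.0 * cv_cm_per_s


# --------------------------------------------------------------------------
# canned experiments
# --------------------------------------------------------------------------

def run_cable(length_cm: float = 3.0,
              params: ModelParameters | None = None,
              duration: float = 150.0,
              pacing_cl: float | None = None,
              n_beats: int = 1,
              stim_amplitude: float = 70.0,
              stim_duration: float = 4.0,
              stim_width_nodes: int = 5,
              probe_positions_cm: tuple[float, ...] = (1.0, 2.0),
              dx: float = 0.022, dt: float = 0.02,
              probe_every: float = 0.05):
    """Stimulate one end of a cable and record V at probe positions.

    With ``pacing_cl`` set, ``n_beats`` pulses are delivered at that cycle
    length (ms); otherwise a single pulse at t = 1 ms.  Returns
    ``(times, probe_V, probe_positions_cm, field)``.
    """
    params = params or ModelParameters()
    nx = int(round(length_cm / dx)) + 1
    field = TissueField(nx, 1, params, dx=dx, dt=dt)
    if pacing_cl is None:
        starts = [1.0]
    else:
        starts = [1.0 + k * pacing_cl for k in range(n_beats)]
    mask = field.column_mask(0, stim_width_nodes)
    stimuli = [StimulusRegion(mask, stim_amplitude, s, stim_duration)
               for s in starts]
    probes = [int(round(x / dx)) for x in probe_positions_cm]
    t, pv, _, _ = field.run(duration, stimuli, probes=probes,
                            probe_every=probe_every)
    return t, pv, tuple(probe_positions_cm), field


def s1s2_crossfield(field: TissueField,
                    s1_amplitude: float = 70.0,
                    s2_amplitude: float = 70.0,
                    stim_duration: float = 4.0,
                    s2_duration: float | None = None,
                    s1_width_nodes: int = 5,
                    duration: float = 2000.0,
                    snapshot_every: float = 10.0,
                    back_threshold: float = BACK_THRESHOLD_MV,
                    s2_delay: float | None = None):
    """Cross-field reentry initiation on a 2D sheet.

    S1 is a line stimulus along the left edge launching a plane wave.  When
    the S1 waveback (repolarisation through ``back_threshold``) crosses the
    domain midline, S2 is fired in the lower half-plane (y below the middle
    row).  ``s2_delay`` overrides the automatic trigger with an explicit S2
    onset time (ms).  Returns ``(snapshot_times, snapshots, s2_time)``;
    ``s2_time`` is None when the waveback never crossed the midline.
    """
    if field.ny < 2:
        raise ValueError("cross-field protocol needs a 2D sheet")
    if s2_duration is None:
        s2_duration = stim_duration
    dt = field.dt
    s1 = StimulusRegion(field.column_mask(0, s1_width_nodes),
                        s1_amplitude, start=1.0, duration=stim_duration)
    s2_mask = field.half_plane_mask(field.ny // 2)
    mid_idx = field.ny // 2 * field.nx + field.nx // 2
    stimuli = [s1]
    s2_time = None
    excited = False
    stimes, snaps = [], []
    sstride = max(int(round(snapshot_every / dt)), 1)
    nstep = int(round(duration / dt))
    if s2_delay is not None:
        s2_time = float(s2_delay)
        stimuli.append(StimulusRegion(s2_mask, s2_amplitude, s2_time,
                                      s2_duration))
    for k in range(nstep):
        if k % sstride == 0:
            stimes.append(field.time)
            snaps.append(field.V.copy())
        v_mid = field.S[L.IV, mid_idx]
        if s2_delay is None and s2_time is None:
            if v_mid > FRONT_THRESHOLD_MV:
                excited = True
            elif excited and v_mid < back_threshold:
                s2_time = field.time
                stimuli.append(StimulusRegion(s2_mask, s2_amplitude,
                                              s2_time, s2_duration))
        field.step(stimuli)
        if k % 500 == 0 and not np.isfinite(field.S[L.IV]).all():
            raise FloatingPointError(
                f"tissue simulation diverged at t = {field.time:.2f} ms")
    return np.asarray(stimes), np.asarray(snaps), s2_time


def paced_wavelength(params: ModelParameters | None = None,
                     pacing_cl: float = 1000.0,
                     n_beats: int = 3,
                     length_cm: float = 11.26,
                     probe_positions_cm: tuple[float, float, float]
                     = (4.0, 5.5, 7.0),
                     dx: float = 0.022, dt: float = 0.02) -> dict:
    """Wavelength of a paced plane wave at steady pacing.

    Paces one end of a cable at ``pacing_cl`` for ``n_beats``; CV is taken
    from front arrivals at the outer probes and WL from the front/back
    crossing times at the middle probe, both for the last captured beat.
    Returns ``{"cv_cm_per_s", "wavelength_cm", "n_nodes", "n_fronts"}``.
    """
    params = params or ModelParameters()
    duration = n_beats * pacing_cl + 400.0
    t, pv, pos, _ = run_cable(length_cm, params, duration=duration,
                              pacing_cl=pacing_cl, n_beats=n_beats,
                              probe_positions_cm=probe_positions_cm,
                              dx=dx, dt=dt, probe_every=0.1)
    v_mid = pv[:, 1]
    ups = np.flatnonzero((v_mid[:-1] < FRONT_THRESHOLD_MV)
                         & (v_mid[1:] >= FRONT_THRESHOLD_MV))
    if len(ups) == 0:
        raise ValueError("no wavefront reached the middle probe")
    t_last = t[ups[-1]]
    span = probe_positions_cm[2] - probe_positions_cm[0]
    lead = span / 0.04 + 10.0  # generous transit-time window before t_last
    t0 = _crossing_time(t, pv[:, 0], FRONT_THRESHOLD_MV, True, t_last - lead)
    t2 = _crossing_time(t, pv[:, 2], FRONT_THRESHOLD_MV, True, t_last - lead)
    cv = span / (t2 - t0) * 1000.0
    wl = measure_wavelength(t, v_mid, cv, t_after=t_last - 5.0)
    return {"cv_cm_per_s": cv, "wavelength_cm": wl,
            "n_nodes": int(round(length_cm / dx)) + 1,
            "n_fronts": int(len(ups))}
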