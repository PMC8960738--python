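"""Synthetic fields and trajectories with known ground truth.

These generators provide analytic stand-ins for expensive tissue
simulations: rotating spiral voltage patterns with a known core, phase
fields with a prescribed number of singularities, hypocycloidal tip paths
with prescribed signed frequencies, and rectangular AP trains.  They are
used as oracles by the test suite and by the packaged mini fixtures; they
are synthetic by construction, not model output.
"""

from __future__ import annotations

import numpy as np

from .spiral_analysis import TipTrajectory

__all__ = [
    "spiral_voltage_frames", "multi_singularity_frames",
    "hypocycloid_trajectory", "plane_wave_frames", "square_pulse_trace",
    "ap_train_frames",
]


def spiral_voltage_frames(n: int = 96, dx: float = 0.022,
                          core: tuple[float, float] | None = None,
                          period_ms: float = 180.0,
                          wavelength_cm: float = 2.0,
                          times_ms=np.arange(0.0, 100.0, 10.0),
                          v_rest: float = -85.0, v_peak: float = 15.0,
                          core_radius_cm: float | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Archimedean spiral voltage pattern rotating about a known core.

    ``V = v_rest + (v_peak - v_rest) * env(r) * (1 + cos(theta - k r - w t))/2``
    with an amplitude envelope ``env(r) = 1 - exp(-r/r0)`` that pins the
    phase-singular point at the core.  Returns ``(times, frames)`` with
    frames shaped (len(times), n, n).
    """
    x = np.arange(n) * dx
    X, Y = np.meshgrid(x, x)
    if core is None:
        core = (x[n // 2], x[n // 2])
    r0 = core_radius_cm if core_radius_cm is not None else dx
    R = np.hypot(X - core[0], Y - core[1])
    TH = np.arctan2(Y - core[1], X - core[0])
    k = 2.0 * np.pi / wavelength_cm
    w = 2.0 * np.pi / period_ms
    env = 1.0 - np.exp(-R / r0)
    times_ms = np.asarray(times_ms, dtype=float)
    frames = np.empty((len(times_ms), n, n))
    for i, t in enumerate(times_ms):
        frames[i] = v_rest + (v_peak - v_rest) * env \
            * 0.5 * (1.0 + np.cos(TH - k * R - w * t))
    return times_ms, frames


def multi_singularity_frames(cores, charges, n: int = 128,
                             dx: float = 0.022,
                             times_ms=np.arange(0.0, 40.0, 10.0),
                             period_ms: float = 180.0,
                             v_star: float = -35.0,
                             amplitude: float = 45.0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Voltage movie whose phase field carries prescribed singularities.

    The phase is ``Phi(x, y) = sum_i q_i * atan2(y - y_i, x - x_i)`` and the
    voltage ``V = v_star + A cos(Phi - w t)``, so the phase-winding census
    should report ``sum(|q_i|)`` singularities in every frame.
    """
    x = np.arange(n) * dx
    X, Y = np.meshgrid(x, x)
    phi = np.zeros((n, n))
    for (cx, cy), q in zip(cores, charges):
        phi += q * np.arctan2(Y - cy, X - cx)
    w = 2.0 * np.pi / period_ms
    times_ms = np.asarray(times_ms, dtype=float)
    frames = np.empty((len(times_ms), n, n))
    for i, t in enumerate(times_ms):
        frames[i] = v_star + amplitude * np.cos(phi - w * t)
    return times_ms, frames


def plane_wave_frames(n: int = 64, dx: float = 0.022,
                      speed_cm_per_ms: float = 0.058,
                      width_cm: float = 1.0,
                      times_ms=np.arange(0.0, 30.0, 10.0),
                      v_rest: float = -80.0, v_peak: float = 20.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Rightward-travelling rectangular excitation band (no rotation)."""
    x = np.arange(n) * dx
    X = np.tile(x, (n, 1))
    times_ms = np.asarray(times_ms, dtype=float)
    frames = np.full((len(times_ms), n, n), v_rest)
    for i, t in enumerate(times_ms):
        front = 0.3 + speed_cm_per_ms * t
        band = (X <= front) & (X > front - width_cm)
        frames[i][band] = v_peak
    return times_ms, frames


def hypocycloid_trajectory(f0_hz: float = 5.426, f1_hz: float = -3.548,
                           r0_cm: float = 0.5, r1_cm: float = 0.3,
                           duration_ms: float = 4000.0,
                           sampling_interval_ms: float = 10.0,
                           center=(5.6, 5.6),
                           drift_cm_per_s: float = 0.0) -> TipTrajectory:
    """Tip path built from two counter-rotating circular orbits.

    The superposition of orbits at signed frequencies ``f0`` (amplitude
    ``r0``) and ``f1`` (amplitude ``r1``) traces the flower-like hypocycloid
    pattern characteristic of meandering spiral tips; an optional slow drift
    moves the pattern centre.
    """
    t = np.arange(0.0, duration_ms, sampling_interval_ms)
    ts = t / 1000.0
    z = (r0_cm * np.exp(2j * np.pi * f0_hz * ts)
         + r1_cm * np.exp(2j * np.pi * f1_hz * ts)
         + drift_cm_per_s * ts * (1.0 + 1.0j) / np.sqrt(2.0))
    return TipTrajectory(times=t, x=center[0] + z.real, y=center[1] + z.imag,
                         sampling_interval=sampling_interval_ms)


def square_pulse_trace(width_ms: float = 100.0, baseline_mv: float = -80.0,
                       peak_mv: float = 20.0, stim_time: float = 10.0,
                       duration_ms: float = 400.0, dt_ms: float = 0.1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular 'action potential' of exactly ``width_ms`` above baseline."""
    t = np.arange(0.0, duration_ms, dt_ms)
    v = np.full_like(t, baseline_mv)
    v[(t >= stim_time) & (t < stim_time + width_ms)] = peak_mv
    return t, v


def ap_train_frames(apd_sequence_ms, cl_ms: float = 200.0, n: int = 8,
                    dx: float = 0.022, dt_ms: float = 2.0,
                    baseline_mv: float = -80.0, peak_mv: float = 20.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Spatially uniform movie of rectangular APs with prescribed durations.

    Beat ``k`` starts at ``k * cl_ms`` and stays at ``peak_mv`` for
    ``apd_sequence_ms[k]``; used to exercise APD mapping and alternans
    detection with exactly known ground truth.
    """
    apds = list(apd_sequence_ms)
    total = cl_ms * len(apds) + 100.0
    t = np.arange(0.0, total, dt_ms)
    v = np.full_like(t, baseline_mv)
    for k, apd in enumerate(apds):
        s = k * cl_ms + 5.0
        v[(t >= s) & (t < s + apd)] = peak_mv
    frames = np.repeat(v[:, None, None], n, axis=1)
    frames = np.repeat(frames, n, axis=2)
    return t, frames
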