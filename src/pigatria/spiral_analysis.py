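"""Analysis of reentrant activity in field histories.

Spiral-tip detection (intersection of the V = -35 mV isopotential with the
zero contour of the inter-frame voltage difference), tip linking into
trajectories, signed-frequency spectra of the complex tip path, phase-
singularity counting by phase winding, and per-site APD90 mapping with
alternans detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as _skmeasure
from shapely.geometry import LineString

TIP_ISO_MV = -35.0

__all__ = [
    "TipTrajectory", "SpiralMetrics", "track_tip", "link_tips",
    "trajectory_spectrum", "count_phase_singularities",
    "apd_map_and_alternans", "TIP_ISO_MV",
]


@dataclass
class TipTrajectory:
    """Time-stamped spiral tip positions (cm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def complex_path(self) -> np.ndarray:
        return self.x + 1j * self.y


@dataclass
class SpiralMetrics:
    """Derived rotation metrics of a spiral-wave episode."""

    rotation_period: float            # ms, from the dominant frequency
    frequencies: np.ndarray           # Hz, signed, strongest first
    amplitudes: np.ndarray            # same order
    ps_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    petal_count: int | None = None


# --------------------------------------------------------------------------
# tip tracking
# --------------------------------------------------------------------------

def track_tip(V_now: np.ndarray, V_prev: np.ndarray, dx: float,
              iso_mv: float = TIP_ISO_MV) -> list[tuple[float, float]]:
    """Spiral tip positions in one snapshot pair.

    Tips are the sub-grid intersections of the isopotential line
    ``V = iso_mv`` with the zero contour of ``V_now - V_prev`` (the
    discrete stand-in for dV/dt = 0), both obtained by marching squares
    (bilinear interpolation within grid cells).  Returns (x, y) in cm;
    empty list when the wave is absent or planar.
    """
    V_now = np.asarray(V_now, dtype=float)
    V_prev = np.asarray(V_prev, dtype=float)
    if V_now.shape != V_prev.shape:
        raise ValueError("snapshot pair must be co-registered")
    iso = _skmeasure.find_contours(V_now, iso_mv)
    dvdt0 = _skmeasure.find_contours(V_now - V_prev, 0.0)
    tips: list[tuple[float, float]] = []
    iso_lines = [LineString(c[:, ::-1]) for c in iso if len(c) > 1]
    dv_lines = [LineString(c[:, ::-1]) for c in dvdt0 if len(c) > 1]
    for a in iso_lines:
        for b in dv_lines:
            inter = a.intersection(b)
            if inter.is_empty:
                continue
            for geom in getattr(inter, "geoms", [inter]):
                if geom.geom_type == "Point":
                    tips.append((geom.x * dx, geom.y * dx))
                else:  # grazing overlap: use the representative point
                    rp = geom.representative_point()
                    tips.append((rp.x * dx, rp.y * dx))
    return tips


def link_tips(snapshot_times: np.ndarray, tip_lists,
              gate_cm_per_frame: float = 1.0) -> list[TipTrajectory]:
    """Link per-frame tip detections into trajectories.

    Nearest-neighbour continuity with a displacement gate (default 1 cm per
    frame, matching the 10 ms snapshot cadence); detections beyond the gate
    spawn new tracks.  Returns trajectories sorted by length (longest
    first).
    """
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    open_tracks: list[dict] = []
    done: list[dict] = []
    for t, tips in zip(snapshot_times, tip_lists):
        tips = list(tips)
        used = [False] * len(tips)
        for tr in list(open_tracks):
            if not tips:
                open_tracks.remove(tr)
                done.append(tr)
                continue
            px, py = tr["x"][-1], tr["y"][-1]
            d2 = [(i, (x - px) ** 2 + (y - py) ** 2)
                  for i, (x, y) in enumerate(tips) if not used[i]]
            if not d2:
                open_tracks.remove(tr)
                done.append(tr)
                continue
            i, best = min(d2, key=lambda q: q[1])
            if best <= gate_cm_per_frame ** 2:
                used[i] = True
                tr["t"].append(t)
                tr["x"].append(tips[i][0])
                tr["y"].append(tips[i][1])
            else:
                open_tracks.remove(tr)
                done.append(tr)
        for i, (x, y) in enumerate(tips):
            if not used[i]:
                open_tracks.append({"t": [t], "x": [x], "y": [y]})
    done.extend(open_tracks)
    dt_snap = float(np.median(np.diff(snapshot_times))) \
        if len(snapshot_times) > 1 else 0.0
    tracks = [TipTrajectory(np.array(tr["t"]), np.array(tr["x"]),
                            np.array(tr["y"]), dt_snap)
              for tr in done if len(tr["t"]) >= 2]
    return sorted(tracks, key=len, reverse=True)


# --------------------------------------------------------------------------
# trajectory spectrum
# --------------------------------------------------------------------------

def trajectory_spectrum(traj: TipTrajectory, n_peaks: int = 4,
                        min_rotations: float = 2.0) -> SpiralMetrics:
    """Signed-frequency spectrum of the tip path.

    The DFT of the mean-removed complex signal x + i*y keeps the rotation
    sense: counter-clockwise orbits appear at positive frequency, clockwise
    at negative.  Peaks are local maxima of the magnitude spectrum refined
    by parabolic interpolation; the ``n_peaks`` strongest are returned and
    the rotation period is taken from the dominant one.
    """
    n = len(traj)
    if n < 8:
        raise ValueError("trajectory too short for spectral analysis")
    dt_s = traj.sampling_interval / 1000.0
    z = traj.complex_path()
    z = z - z.mean()
    spec = np.fft.fft(z)
    freqs = np.fft.fftfreq(n, d=dt_s)
    mag = np.abs(spec)
    # dominant period sanity check: need >= min_rotations in the window
    k0 = int(np.argmax(mag))
    if abs(freqs[k0]) * n * dt_s < min_rotations:
        raise ValueError("trajectory shorter than the requested number of "
                         "rotations at its dominant frequency")
    order = np.argsort(mag)[::-1]
    peaks, amps = [], []
    taken: list[int] = []
    df = freqs[1] - freqs[0]
    for k in order:
        if len(peaks) >= n_peaks:
            break
        if any(min(abs(k - q), n - abs(k - q)) <= 2 for q in taken):
            continue  # same spectral peak
        km, kp = (k - 1) % n, (k + 1) % n
        a, b, c = mag[km], mag[k], mag[kp]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        peaks.append(freqs[k] + delta * df)
        amps.append(float(b))
        taken.append(k)
    peaks = np.asarray(peaks)
    amps = np.asarray(amps)
    period = 1000.0 / abs(peaks[0])
    return SpiralMetrics(rotation_period=period, frequencies=peaks,
                         amplitudes=amps,
                         petal_count=estimate_petal_count(peaks))


def estimate_petal_count(frequencies) -> int | None:
    """Petal count of a two-phasor (hypocycloidal) meander pattern.

    For a tip path dominated by counter-rotating orbits at signed
    frequencies f0 and f1, petals recur at |f0 - f1| while the pattern
    precesses at |f0 + f1|, so the flower closes after about
    |f0 - f1| / |f0 + f1| petals.  Returns None when the two dominant
    components do not counter-rotate."""
    if len(frequencies) < 2:
        return None
    f0, f1 = float(frequencies[0]), float(frequencies[1])
    if f0 * f1 >= 0 or abs(f0 + f1) < 1e-9:
        return None
    return int(round(abs(f0 - f1) / abs(f0 + f1)))


# --------------------------------------------------------------------------
# phase singularities
# --------------------------------------------------------------------------

def count_phase_singularities(snapshots: np.ndarray,
                              v_star: float = TIP_ISO_MV,
                              embed_lag_frames: int = 1) -> np.ndarray:
    """Phase-singularity count per frame.

    The activation phase is embedded as
    ``theta = atan2(V(t) - V*, V(t - lag) - V*)``; a lattice plaquette whose
    wrapped phase differences wind by +/-2*pi contains one singularity
    (spiral tip).  The first ``embed_lag_frames`` frames have no phase and
    are reported as zero.
    """
    snaps = np.asarray(snapshots, dtype=float)
    if snaps.ndim != 3 or snaps.shape[0] < embed_lag_frames + 1:
        raise ValueError("need at least two frames for phase embedding")
    counts = np.zeros(snaps.shape[0], dtype=int)
    for k in range(embed_lag_frames, snaps.shape[0]):
        theta = np.arctan2(snaps[k] - v_star,
                           snaps[k - embed_lag_frames] - v_star)
        d1 = _wrap(theta[:-1, 1:] - theta[:-1, :-1])
        d2 = _wrap(theta[1:, 1:] - theta[:-1, 1:])
        d3 = _wrap(theta[1:, :-1] - theta[1:, 1:])
        d4 = _wrap(theta[:-1, :-1] - theta[1:, :-1])
        winding = d1 + d2 + d3 + d4
        counts[k] = int(np.sum(np.abs(winding) > np.pi))
    return counts


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


# --------------------------------------------------------------------------
# APD mapping and alternans
# --------------------------------------------------------------------------

def apd_map_and_alternans(snapshot_times: np.ndarray, snapshots: np.ndarray,
                          dx: float,
                          sample_stride: int = 8,
                          alternans_threshold_ms: float = 5.0,
                          exclude_center_cm: float | None = None,
                          exclude_points=None,
                          min_beats: int = 4,
                          upstroke_mv: float = TIP_ISO_MV) -> dict:
    """Per-site beat-wise APD90 with alternans flags and restitution pairs.

    V is sampled at every ``sample_stride``-th node in both directions.
    At each site, activations are upstroke crossings of ``upstroke_mv``;
    APD90 is the time to 90% repolarisation between the local diastolic
    minimum and the beat peak; DI is the time from 90% repolarisation to
    the next activation.  Sites within ``exclude_center_cm`` of any point in
    ``exclude_points`` (e.g. a tip trajectory) or with fewer than
    ``min_beats`` activations are excluded.  Alternans is flagged where some
    consecutive-beat |dAPD90| exceeds the threshold.

    Returns a dict with per-site records and pooled (CL, APD90) and
    (DI, APD90) restitution pairs.
    """
    t = np.asarray(snapshot_times, dtype=float)
    snaps = np.asarray(snapshots, dtype=float)
    ny, nx = snaps.shape[1:]
    sites = [(iy, ix) for iy in range(0, ny, sample_stride)
             for ix in range(0, nx, sample_stride)]
    if exclude_points is not None and exclude_center_cm:
        pts = np.asarray(exclude_points, dtype=float).reshape(-1, 2)
        keep = []
        for iy, ix in sites:
            xy = np.array([ix * dx, iy * dx])
            if np.min(np.hypot(*(pts - xy).T)) > exclude_center_cm:
                keep.append((iy, ix))
        sites = keep

    records = []
    cl_apd, di_apd = [], []
    for iy, ix in sites:
        v = snaps[:, iy, ix]
        ups = np.flatnonzero((v[:-1] < upstroke_mv) & (v[1:] >= upstroke_mv))
        if len(ups) < min_beats:
            continue
        act_times = t[ups]
        apds, apd_ends = [], []
        for b, k in enumerate(ups):
            k_end = ups[b + 1] if b + 1 < len(ups) else len(v) - 1
            k_pre = ups[b - 1] if b > 0 else 0
            vmin = v[k_pre:k + 1].min()
            seg = v[k:k_end + 1]
            k_pk = k + int(np.argmax(seg))
            vmax = v[k_pk]
            lvl = vmax - 0.9 * (vmax - vmin)
            below = np.flatnonzero(v[k_pk:k_end + 1] < lvl)
            if below.size == 0:
                apds.append(np.nan)
                apd_ends.append(np.nan)
                continue
            kk = k_pk + below[0]
            t_rep = np.interp(lvl, [v[kk], v[kk - 1]], [t[kk], t[kk - 1]])
            apds.append(t_rep - act_times[b])
            apd_ends.append(t_rep)
        apds = np.asarray(apds)
        cls = np.diff(act_times)
        dis = act_times[1:] - np.asarray(apd_ends)[:-1]
        dapd = np.abs(np.diff(apds))
        flag = bool(np.nanmax(dapd) > alternans_threshold_ms) \
            if dapd.size else False
        records.append({"site": (iy, ix), "x_cm": ix * dx, "y_cm": iy * dx,
                        "activation_times": act_times, "apd90": apds,
                        "cl": cls, "di": dis, "alternans": flag})
        good = ~np.isnan(apds[1:])
        cl_apd.extend(zip(cls[good], apds[1:][good]))
        di_apd.extend(zip(dis[good], apds[1:][good]))
    return {
        "sites": records,
        "cl_apd90": np.asarray(cl_apd, dtype=float).reshape(-1, 2),
        "di_apd90": np.asarray(di_apd, dtype=float).reshape(-1, 2),
        "alternans_fraction": (float(np.mean([r["alternans"]
                                              for r in records]))
                               if records else float("nan")),
    }
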