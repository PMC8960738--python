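"""Small static plot helpers (matplotlib)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_trace(trace, currents=(), ax=None):
    """Membrane potential (and optionally currents) of a 0-D run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.times, trace.V, "k", lw=1)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    if currents:
        cx = ax.twinx()
        cur = trace.currents()
        for name in currents:
            cx.plot(trace.times, cur[name], lw=0.8, label=name)
        cx.set_ylabel("current (pA/pF)")
        cx.legend(fontsize=7)
    return ax


def plot_iv(df, ax=None, **kwargs):
    """IV curve from a voltage-clamp result table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(df.V_test, df.current, "o-", ms=3, **kwargs)
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel("test potential (mV)")
    ax.set_ylabel("current (pA/pF)")
    return ax


def plot_tip_trajectory(traj, ax=None):
    """Spiral tip path in the tissue plane."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(traj.x, traj.y, lw=0.7)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    return ax
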