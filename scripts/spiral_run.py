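#!/usr/bin/env python
"""Full-resolution spiral-wave experiments (long; hours on one CPU).

Reproduces the three 2D reentry studies at native resolution
(512 x 512 nodes = 11.26 x 11.26 cm, dx = 0.022 cm, dt = 0.02 ms):

  baseline   S1-S2 cross-field initiation of a single spiral, followed by
             tip tracking, the signed-frequency spectrum and the
             phase-singularity census;
  clblock    the same with I_ClCa reduced (50% or 90% block) to replay the
             alternans-persistence experiment;
  breakup    g_Kr at a quarter of its fitted value: the multi-wavelet
             (fibrillation-like) state with a sustained singularity count.

Example:

    python scripts/spiral_run.py baseline --tmax 40000 --out scratch/spiral

These runs are deliberately not part of the test suite or the acceptance
script; use them to regenerate the long-run statistics.
"""

from __future__ import annotations

import argparse
import os

import numpy as np
import pandas as pd

from pigatria import ModelParameters
from pigatria.io_config import save_history, write_csv_atomic
from pigatria.spiral_analysis import (count_phase_singularities, link_tips,
                                      track_tip, trajectory_spectrum)
from pigatria.tissue import TissueField, s1s2_crossfield


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("mode", choices=["baseline", "clblock", "breakup"])
    ap.add_argument("--tmax", type=float, default=40_000.0)
    ap.add_argument("--n", type=int, default=512)
    ap.add_argument("--block", type=float, default=0.5,
                    help="I_ClCa block fraction for clblock mode")
    ap.add_argument("--snapshot-every", type=float, default=10.0)
    ap.add_argument("--out", default="scratch/spiral")
    args = ap.parse_args()

    base = ModelParameters()
    if args.mode == "breakup":
        params = base.replace(g_Kr=0.25 * base.g_Kr)
    elif args.mode == "clblock":
        params = base.replace(g_ClCa=(1.0 - args.block) * base.g_ClCa)
    else:
        params = base

    os.makedirs(args.out, exist_ok=True)
    field = TissueField(args.n, args.n, params)
    times, snaps, s2_time = s1s2_crossfield(
        field, duration=args.tmax, snapshot_every=args.snapshot_every)
    save_history(os.path.join(args.out, f"{args.mode}.h5"), times, snaps,
                 field.dx, field.dt,
                 s2_time_ms=s2_time if s2_time is not None else -1.0,
                 mode=args.mode)

    tips = [track_tip(snaps[k], snaps[k - 1], field.dx)
            for k in range(1, len(snaps))]
    tracks = link_tips(times[1:], tips)
    if tracks:
        traj = tracks[0]
        write_csv_atomic(pd.DataFrame({"time_ms": traj.times,
                                       "x_cm": traj.x, "y_cm": traj.y}),
                         os.path.join(args.out, "tip_trajectory.csv"))
        if len(traj) >= 8:
            m = trajectory_spectrum(traj)
            print(f"rotation period {m.rotation_period:.1f} ms; "
                  f"signed peaks {np.round(m.frequencies, 3)} Hz")
    counts = count_phase_singularities(snaps)
    write_csv_atomic(pd.DataFrame({"time_ms": times, "ps_count": counts}),
                     os.path.join(args.out, "ps_counts.csv"))
    print(f"S2 at {s2_time} ms; sustained PS count (last 20 frames): "
          f"{counts[-20:].mean():.1f}")


if __name__ == "__main__":
    main()
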