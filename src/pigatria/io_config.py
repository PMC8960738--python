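"""Experiment configuration, file I/O and fixture generation.

One experiment = one config file = one output directory.  Configs are YAML
with sections ``experiment``, ``parameters``, ``protocol``, ``grid``,
``integration``, ``output`` and an optional ``seed`` (reserved: the model is
fully deterministic).  Unknown keys are rejected.  Numeric outputs are
columnar text (CSV); field histories go into an HDF5 container.  Every
output directory carries a log with the config hash so runs are
reproducible and attributable.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import _layout as L
from .parameters import ModelParameters
from .state import CellState, resting_state
from .protocols import (ClampProtocol, run_voltage_clamp, run_restitution,
                        measure_erp)
from .tissue import (TissueField, run_cable, measure_cv, measure_wavelength,
                     s1s2_crossfield, _crossing_time)
from .synthetic import spiral_voltage_frames

_SECTIONS = {"experiment", "parameters", "protocol", "grid", "integration",
             "output", "seed"}

__all__ = ["ExperimentConfig", "load_config", "run_experiment",
           "generate_fixtures", "save_history", "load_history",
           "write_csv_atomic"]


@dataclass
class ExperimentConfig:
    """Validated experiment description (see module docstring)."""

    experiment: str
    parameters: dict = dc_field(default_factory=dict)
    protocol: dict = dc_field(default_factory=dict)
    grid: dict = dc_field(default_factory=dict)
    integration: dict = dc_field(default_factory=dict)
    output: dict = dc_field(default_factory=dict)
    seed: int | None = None

    _EXPERIMENTS = ("clamp", "restitution", "erp", "cable", "s1s2")

    def __post_init__(self) -> None:
        if self.experiment not in self._EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose one of {self._EXPERIMENTS}")
        # parameter overrides validated by construction
        self.model_parameters()

    def model_parameters(self) -> ModelParameters:
        return ModelParameters().replace(**self.parameters)

    def to_dict(self) -> dict:
        return {"experiment": self.experiment, "parameters": self.parameters,
                "protocol": self.protocol, "grid": self.grid,
                "integration": self.integration, "output": self.output,
                "seed": self.seed}

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - _SECTIONS
    if unknown:
        raise KeyError(f"unknown config section(s): {sorted(unknown)}")
    if "experiment" not in doc:
        raise KeyError("config must name an 'experiment'")
    return ExperimentConfig(**doc)


# --------------------------------------------------------------------------
# atomic writers / containers
# --------------------------------------------------------------------------

def write_csv_atomic(df: pd.DataFrame, path, **meta) -> None:
    """Write a DataFrame as CSV with ``# key: value`` header lines, renaming
    into place only after the write completes."""
    path = str(path)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    os.replace(tmp, path)


def save_history(path, times: np.ndarray, frames: np.ndarray,
                 dx: float, dt: float, **attrs) -> None:
    """Field history (V per frame) into an HDF5 container."""
    path = str(path)
    tmp = path + ".tmp"
    with h5py.File(tmp, "w") as h5:
        h5.create_dataset("times", data=np.asarray(times))
        h5.create_dataset("V", data=np.asarray(frames),
                          compression="gzip", compression_opts=4)
        h5.attrs["dx_cm"] = dx
        h5.attrs["dt_ms"] = dt
        h5.attrs["package_version"] = _pkg_version
        for k, v in attrs.items():
            h5.attrs[k] = v
    os.replace(tmp, path)


def load_history(path):
    with h5py.File(path, "r") as h5:
        times = h5["times"][...]
        frames = h5["V"][...]
        attrs = dict(h5.attrs)
    return times, frames, attrs


# --------------------------------------------------------------------------
# experiment dispatch
# --------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Execute the configured experiment end-to-end.

    Writes results (CSV / HDF5) plus ``run.log`` into the output directory
    and returns a summary dict.
    """
    t_start = time.time()
    outdir = outdir or config.output.get("dir", "results")
    os.makedirs(outdir, exist_ok=True)
    params = config.model_parameters()
    proto = dict(config.protocol)
    meta = {"config_hash": config.config_hash(),
            "package_version": _pkg_version}
    summary: dict = {"experiment": config.experiment, **meta}

    if config.experiment == "clamp":
        prot = ClampProtocol(
            test_potentials=tuple(proto.get("test_potentials",
                                            range(-40, 61, 5))),
            holding_potential=proto.get("holding_potential", -80.0),
            step_duration=proto.get("step_duration", 300.0),
            interpulse_interval=proto.get("interpulse_interval", 1000.0),
            measured_current=proto.get("current", "I_CaL"),
            measurement_rule=proto.get("measurement_rule", "peak"),
            cai_clamp=proto.get("cai_clamp"))
        df = run_voltage_clamp(prot, params,
                               dt=config.integration.get("dt", 0.02))
        write_csv_atomic(df, os.path.join(outdir, "iv.csv"), **meta)
        summary["iv"] = df

    elif config.experiment == "restitution":
        freqs = proto.get("frequencies", (0.25, 0.5, 1.0, 2.0, 3.0, 4.0))
        df = run_restitution(freqs, params,
                             n_beats=proto.get("n_beats", 12),
                             n_average=proto.get("n_average", 10),
                             dt=config.integration.get("dt", 0.02))
        write_csv_atomic(df, os.path.join(outdir, "restitution.csv"), **meta)
        summary["restitution"] = df

    elif config.experiment == "erp":
        erp = measure_erp(params,
                          s1_count=proto.get("s1_count", 6),
                          s1_cl=proto.get("s1_cl", 1000.0),
                          dt=config.integration.get("dt", 0.02))
        summary["erp_ms"] = erp
        write_csv_atomic(pd.DataFrame([{"ERP_ms": erp}]),
                         os.path.join(outdir, "erp.csv"), **meta)

    elif config.experiment == "cable":
        times, pv, pos, field = run_cable(
            length_cm=config.grid.get("length_cm", 3.0),
            params=params,
            duration=proto.get("duration", 150.0),
            pacing_cl=proto.get("pacing_cl"),
            n_beats=proto.get("n_beats", 1),
            probe_positions_cm=tuple(proto.get("probes", (1.0, 2.0))),
            dx=config.grid.get("dx", 0.022),
            dt=config.integration.get("dt", 0.02))
        cv = measure_cv(times, pv[:, :2], pos[:2])
        summary["cv_cm_per_s"] = cv
        df = pd.DataFrame(pv, columns=[f"V_at_{x}cm" for x in pos])
        df.insert(0, "time_ms", times)
        write_csv_atomic(df, os.path.join(outdir, "cable_probes.csv"),
                         cv_cm_per_s=cv, **meta)

    elif config.experiment == "s1s2":
        nx = config.grid.get("nx", 512)
        ny = config.grid.get("ny", 512)
        field = TissueField(nx, ny, params,
                            dx=config.grid.get("dx", 0.022),
                            dt=config.integration.get("dt", 0.02))
        stimes, snaps, s2_time = s1s2_crossfield(
            field,
            duration=proto.get("duration", 2000.0),
            snapshot_every=proto.get("snapshot_every", 10.0),
            s2_delay=proto.get("s2_delay"))
        summary["s2_time_ms"] = s2_time
        summary["reentry_attempted"] = s2_time is not None
        save_history(os.path.join(outdir, "run.h5"), stimes, snaps,
                     field.dx, field.dt, s2_time_ms=s2_time or -1.0, **meta)

    summary["wall_time_s"] = time.time() - t_start
    log = {k: v for k, v in summary.items()
           if isinstance(v, (str, int, float, bool, type(None)))}
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        json.dump(log, fh, indent=1, default=float)
    return summary


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def generate_fixtures(kind: str, outdir) -> list[str]:
    """Deterministic small artifacts for tests and demos.

    Kinds: ``resting_state`` (equilibrated state as JSON), ``clamp_traces``
    (I_CaL and I_ClCa IV curves at 5 mV steps), ``short_cable`` (probe
    traces of a 3 cm cable run), ``mini_spiral`` (synthetic rotating-spiral
    history; analytic pattern, not model output).
    """
    os.makedirs(outdir, exist_ok=True)
    params = ModelParameters()
    written: list[str] = []

    if kind == "resting_state":
        st = resting_state(params)
        path = os.path.join(outdir, "resting_state.json")
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(st.to_dict(), fh, indent=1)
        os.replace(tmp, path)
        written.append(path)

    elif kind == "clamp_traces":
        for current, cai in (("I_CaL", 0.0001), ("I_ClCa", None)):
            prot = ClampProtocol(test_potentials=tuple(range(-40, 61, 5)),
                                 measured_current=current, cai_clamp=cai)
            df = run_voltage_clamp(prot, params)
            path = os.path.join(outdir, f"iv_{current.lower()}.csv")
            write_csv_atomic(df, path, current=current)
            written.append(path)

    elif kind == "short_cable":
        times, pv, pos, _ = run_cable(3.0, params, duration=120.0,
                                      probe_positions_cm=(1.0, 2.0))
        cv = measure_cv(times, pv, pos)
        df = pd.DataFrame({"time_ms": times, "V_1cm": pv[:, 0],
                           "V_2cm": pv[:, 1]})
        path = os.path.join(outdir, "short_cable.csv")
        write_csv_atomic(df, path, cv_cm_per_s=cv)
        written.append(path)

    elif kind == "mini_spiral":
        times, frames = spiral_voltage_frames(
            n=96, dx=0.022, period_ms=180.0,
            times_ms=np.arange(0.0, 400.0, 10.0))
        path = os.path.join(outdir, "mini_spiral_synthetic.h5")
        save_history(path, times, frames, 0.022, 10.0,
                     synthetic=True, period_ms=180.0)
        written.append(path)

    else:
        raise KeyError(f"unknown fixture kind {kind!r}")
    return written


def save_checkpoint(path, field) -> None:
    """Full-state checkpoint of a tissue field (all state variables)."""
    path = str(path)
    tmp = path + ".tmp"
    with h5py.File(tmp, "w") as h5:
        h5.create_dataset("state", data=field.S, compression="gzip")
        h5.attrs.update({"nx": field.nx, "ny": field.ny, "dx_cm": field.dx,
                         "dt_ms": field.dt, "time_ms": field.time,
                         "package_version": _pkg_version})
        h5.create_dataset("parameters",
                          data=np.void(json.dumps(
                              field.params.to_dict()).encode()))
    os.replace(tmp, path)


def load_checkpoint(path):
    """Restore a tissue field saved by :func:`save_checkpoint`."""
    from .tissue import TissueField

    with h5py.File(path, "r") as h5:
        S = h5["state"][...]
        attrs = dict(h5.attrs)
        pdict = json.loads(bytes(h5["parameters"][()]).decode())
    field = TissueField(int(attrs["nx"]), int(attrs["ny"]),
                        ModelParameters.from_dict(pdict),
                        dx=float(attrs["dx_cm"]), dt=float(attrs["dt_ms"]))
    field.S = S
    field.time = float(attrs["time_ms"])
    return field
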