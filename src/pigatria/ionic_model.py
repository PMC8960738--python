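"""Ionic membrane currents, gate kinetics and single-cell integration.

The membrane obeys ``dV/dt = -(I_ion + I_stim)/C_m`` with ``I_ion`` the sum
of 12 sarcolemmal currents (fast Na+, inward-rectifier K+, Ca-activated Cl-,
ultrarapid / rapid / slow delayed-rectifier K+, L-type Ca2+, Ca2+ pump,
Na/K pump, Na/Ca exchanger and two background currents).  Uniquely for the
pig atrium the entire transient outward current is the Ca2+-activated Cl-
current I_ClCa, gated by the myoplasmic Ca2+ flux F_n.  Subcellular Ca2+
uptake/release keeps the classic two-compartment SR scheme (uptake, release,
transfer and leak fluxes, rapid-equilibrium buffering).

All public functions are thin wrappers over the jitted kernel in
:mod:`pigatria._kernel`, so single-step calls, long 0-D runs and the tissue
solver share one implementation of the model equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _layout as L
from . import _kernel as K
from .constants import BODY_TEMPERATURE, FARADAY, R_GAS
from .parameters import ModelParameters, DEFAULT_PARAMETERS
from .state import CellState, SOURCE_MODEL_INITIAL_STATE, resting_state

__all__ = [
    "ModelParameters", "CellState", "CurrentSet", "CellTrace",
    "nernst_potential", "gate_kinetics", "compute_currents",
    "compute_fn_and_qca", "step_ca_subsystem", "step_cell", "simulate_cell",
    "resting_state", "SOURCE_MODEL_INITIAL_STATE",
]


def nernst_potential(valence: int, conc_in: float, conc_out: float,
                     temperature: float = BODY_TEMPERATURE) -> float:
    """Equilibrium (Nernst) potential in mV.

    Parameters are the ionic valence, intra- and extracellular
    concentrations (mM) and the absolute temperature (K).
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be strictly positive")
    return (R_GAS * temperature) / (valence * FARADAY) * math.log(conc_out / conc_in)


# --------------------------------------------------------------------------
# gate kinetics
# --------------------------------------------------------------------------

_VOLTAGE_GATES = ("m", "h", "j", "d", "f", "u_a", "u_if", "u_is",
                  "x_r", "x_s", "w")
_FLUX_GATES = ("q_ca", "u", "v")


def gate_kinetics(gate_id: str, x: float,
                  params: ModelParameters | None = None) -> tuple[float, float]:
    """Steady state and time constant (ms) of one gate.

    ``x`` is the gate's controlling variable: membrane potential in mV for
    the voltage gates, [Ca2+]_i in mM for ``f_ca``, and the myoplasmic Ca2+
    flux F_n for ``q_ca``, ``u`` and ``v``.
    """
    p = (params or DEFAULT_PARAMETERS).pack()
    if gate_id in ("m", "h", "j"):
        res = K._sodium_gates(float(x), p)
        k = {"m": 0, "h": 2, "j": 4}[gate_id]
        return res[k], res[k + 1]
    if gate_id in ("d", "f"):
        res = K._ical_gates(float(x), p)
        k = {"d": 0, "f": 2}[gate_id]
        return res[k], res[k + 1]
    if gate_id in ("u_a", "u_if", "u_is"):
        ua_inf, tau_ua, ui_inf, tau_uif, tau_uis = K._kur_gates(float(x), p)
        return {"u_a": (ua_inf, tau_ua),
                "u_if": (ui_inf, tau_uif),
                "u_is": (ui_inf, tau_uis)}[gate_id]
    if gate_id == "x_r":
        return K._xr_gate(float(x), p)
    if gate_id == "x_s":
        return K._xs_gate(float(x), p)
    if gate_id == "w":
        return K._w_gate(float(x), p)
    if gate_id == "f_ca":
        return K._fca_gate(float(x), p)
    if gate_id in _FLUX_GATES:
        u_inf, tau_u, v_inf, tau_v, qca_inf, tau_qca = K._fn_gates(float(x), 0.0, p)
        return {"u": (u_inf, tau_u), "v": (v_inf, tau_v),
                "q_ca": (qca_inf, tau_qca)}[gate_id]
    raise KeyError(f"unknown gate id: {gate_id!r}")


# --------------------------------------------------------------------------
# currents
# --------------------------------------------------------------------------

@dataclass
class CurrentSet:
    """All membrane currents (pA/pF), SR fluxes (mM/ms) and F_n at one state."""

    I_Na: float
    I_K1: float
    I_ClCa: float
    I_Kur: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_pCa: float
    I_NaK: float
    I_NaCa: float
    I_bNa: float
    I_bCa: float
    I_up: float
    I_rel: float
    I_tr: float
    I_up_leak: float
    F_n: float
    I_ion: float

    def membrane_sum(self) -> float:
        return (self.I_Na + self.I_K1 + self.I_ClCa + self.I_Kur + self.I_Kr
                + self.I_Ks + self.I_CaL + self.I_pCa + self.I_NaK
                + self.I_NaCa + self.I_bNa + self.I_bCa)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_currents(state: CellState,
                     params: ModelParameters | None = None) -> CurrentSet:
    """Evaluate every current at one state (the 12 membrane currents sum to
    ``I_ion`` by construction)."""
    p = (params or DEFAULT_PARAMETERS).pack()
    out = np.empty((L.NCUR, 1), dtype=np.float64)
    K.currents_cells(state.as_array(), p, out)
    return CurrentSet(*[float(out[k, 0]) for k in range(L.NCUR)])


def currents_from_states(states: np.ndarray,
                         params: ModelParameters | None = None) -> dict:
    """Vectorised currents for a (n, NVAR) array of recorded states."""
    p = (params or DEFAULT_PARAMETERS).pack()
    S = np.ascontiguousarray(np.asarray(states, dtype=np.float64).T)
    out = np.empty((L.NCUR, S.shape[1]), dtype=np.float64)
    K.currents_cells(S, p, out)
    return {name: out[k].copy() for k, name in enumerate(L.CURRENT_NAMES)}


def compute_fn_and_qca(state: CellState, currents: CurrentSet,
                       params: ModelParameters | None = None
                       ) -> tuple[float, float, float]:
    """Myoplasmic Ca2+ flux F_n, the q_Ca steady state it drives, and the
    q_Ca time constant (2 ms).

    ``F_n`` combines SR release with the L-type / exchanger trigger fluxes;
    q_Ca follows a cubic Hill curve in F_n (half-point ``qca_fn_half``),
    clipped at zero for inward-trigger-dominated (negative) flux.
    """
    pr = params or DEFAULT_PARAMETERS
    fn = (1.0e-12 * pr.V_rel * currents.I_rel
          - (5.0e-13 / FARADAY)
          * (0.5 * currents.I_CaL - 0.2 * currents.I_NaCa) * pr.C_m)
    x = max(fn / pr.qca_fn_half, 0.0)
    qca_inf = 1.0 - 1.0 / (1.0 + x ** 3)
    return fn, qca_inf, 2.0


# --------------------------------------------------------------------------
# time stepping
# --------------------------------------------------------------------------

def step_ca_subsystem(state: CellState, currents: CurrentSet, dt: float,
                      params: ModelParameters | None = None) -> CellState:
    """Advance the Ca2+ subsystem ([Ca]_i, [Ca]_up, [Ca]_rel and the SR gates
    u, v, w, plus q_ca and f_ca) by one Euler step, holding V and the other
    gates fixed and using the fluxes supplied in ``currents``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    pr = params or DEFAULT_PARAMETERS
    p = pr.pack()
    s = state.to_dict()

    b1 = (pr.C_m * (2.0 * currents.I_NaCa - currents.I_pCa - currents.I_CaL
                    - currents.I_bCa) / (2.0 * FARADAY * pr.V_i)
          + (pr.V_up * (currents.I_up_leak - currents.I_up)
             + currents.I_rel * pr.V_rel) / pr.V_i)
    b2 = (1.0 + pr.trpn_max * pr.Km_trpn / (state.Ca_i + pr.Km_trpn) ** 2
          + pr.cmdn_max * pr.Km_cmdn / (state.Ca_i + pr.Km_cmdn) ** 2)
    csqn_b = 1.0 + pr.csqn_max * pr.Km_csqn / (state.Ca_rel + pr.Km_csqn) ** 2

    s["Ca_i"] = state.Ca_i + dt * b1 / b2
    s["Ca_up"] = state.Ca_up + dt * (currents.I_up - currents.I_up_leak
                                     - currents.I_tr * pr.V_rel / pr.V_up)
    s["Ca_rel"] = state.Ca_rel + dt * (currents.I_tr - currents.I_rel) / csqn_b

    fn, qca_inf, tau_qca = compute_fn_and_qca(state, currents, pr)
    u_inf, tau_u, v_inf, tau_v, _, _ = K._fn_gates(fn, state.V, p)
    w_inf, tau_w = K._w_gate(state.V, p)
    fca_inf, tau_fca = K._fca_gate(state.Ca_i, p)
    s["u"] = state.u + dt * (u_inf - state.u) / tau_u
    s["v"] = state.v + dt * (v_inf - state.v) / tau_v
    s["w"] = state.w + dt * (w_inf - state.w) / tau_w
    s["q_ca"] = state.q_ca + dt * (qca_inf - state.q_ca) / tau_qca
    s["f_ca"] = state.f_ca + dt * (fca_inf - state.f_ca) / tau_fca

    new = CellState(**s)
    for name in ("Ca_i", "Ca_up", "Ca_rel"):
        if getattr(new, name) <= 0:
            raise FloatingPointError(
                f"numerical instability: {name} became non-positive")
    return new


def step_cell(state: CellState, params: ModelParameters | None = None,
              I_stim: float = 0.0, dt: float = 0.02,
              scheme: str = "euler") -> CellState:
    """Advance one cell by one time step.

    ``I_stim`` is the stimulus in pA/pF, positive = depolarising.  ``scheme``
    is ``"euler"`` (default, matching the tissue numerics) or
    ``"rush-larsen"`` for exponential gate updates.
    """
    if not 0.0 < dt <= 0.05:
        raise ValueError("dt must lie in (0, 0.05] ms")
    rl = {"euler": 0, "rush-larsen": 1}.get(scheme)
    if rl is None:
        raise ValueError(f"unknown integration scheme {scheme!r}")
    pr = params or DEFAULT_PARAMETERS
    S = state.as_array()
    extra = np.array([I_stim], dtype=np.float64)
    K.step_cells(S, extra, dt, pr.pack(), rl, 0, 0, 1)
    if not np.all(np.isfinite(S)):
        bad = int(np.flatnonzero(~np.isfinite(S[:, 0]))[0])
        raise FloatingPointError(
            f"numerical instability: state variable "
            f"{L.STATE_NAMES[bad]!r} became non-finite")
    return CellState.from_array(S)


@dataclass
class CellTrace:
    """Recorded 0-D run: sample times (ms) and states (n_samples, NVAR)."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    stim_times: tuple = ()

    @property
    def V(self) -> np.ndarray:
        return self.states[:, L.IV]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, L.STATE_NAMES.index(name)]

    def currents(self) -> dict:
        return currents_from_states(self.states, self.params)

    def final_state(self) -> CellState:
        return CellState.from_array(self.states[-1])

    def to_dataframe(self, include_currents: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(L.STATE_NAMES))
        df.insert(0, "time", self.times)
        if include_currents:
            for name, arr in self.currents().items():
                df[name] = arr
        return df


def simulate_cell(params: ModelParameters | None = None,
                  state: CellState | None = None,
                  duration: float = 1000.0,
                  dt: float = 0.02,
                  stim_times: Sequence[float] | Iterable[float] = (),
                  stim_amplitude: float = 70.0,
                  stim_duration: float = 4.0,
                  record_every: float = 0.2,
                  scheme: str = "euler",
                  clamp_cai: bool = False) -> CellTrace:
    """Run one cell for ``duration`` ms with rectangular stimulus pulses.

    ``stim_times`` are pulse onsets (ms); amplitude is in pA/pF (positive =
    depolarising; the tissue-level 7 nA pulse corresponds to 70 pA/pF at
    C_m = 100 pF).  The full state is recorded every ``record_every`` ms.
    """
    pr = params or DEFAULT_PARAMETERS
    st = state if state is not None else resting_state(pr)
    rl = {"euler": 0, "rush-larsen": 1}[scheme]
    nstep = int(round(duration / dt))
    istim = np.zeros(nstep, dtype=np.float64)
    for t0 in stim_times:
        k0 = int(round(t0 / dt))
        k1 = min(int(round((t0 + stim_duration) / dt)), nstep)
        istim[k0:k1] = stim_amplitude
    rec_stride = max(int(round(record_every / dt)), 1)
    nrec = (nstep + rec_stride - 1) // rec_stride
    rec = np.empty((nrec, L.NVAR), dtype=np.float64)
    S = st.as_array()
    try:
        nwritten = K.integrate_cell(S, pr.pack(), dt, istim, rl, 0,
                                    int(clamp_cai), 1, rec_stride, rec)
    except (ZeroDivisionError, OverflowError, ValueError) as exc:
        raise FloatingPointError(
            "numerical instability during cell integration (reduce the "
            "stimulus strength or dt, or use the rush-larsen scheme)"
        ) from exc
    if not np.all(np.isfinite(S)):
        bad = int(np.flatnonzero(~np.isfinite(S[:, 0]))[0])
        raise FloatingPointError(
            f"numerical instability: state variable "
            f"{L.STATE_NAMES[bad]!r} became non-finite")
    times = np.arange(nwritten) * rec_stride * dt
    return CellTrace(times=times, states=rec[:nwritten], params=pr,
                     stim_times=tuple(stim_times))
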