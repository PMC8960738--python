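"""Model parameters for the pig atrial cardiomyocyte.

Defaults are the fitted porcine values for the channel conductances and pump
maxima, with the remaining constants (cell geometry, buffers, SR transport,
exchanger kinetics) carried over from the human-atrial / guinea-pig-ventricle
source formulations the porcine model is built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from . import _layout as L
from .constants import BODY_TEMPERATURE, FARADAY, R_GAS


@dataclass
class ModelParameters:
    """Conductances, maximal pump/exchanger currents and kinetic constants.

    Units: conductances nS/pF, pump maxima pA/pF (``I_NaCa_max`` is the
    exchanger scaling constant), capacitance pF, temperature K,
    concentrations mM, potentials mV, diffusion cm^2/ms.
    """

    # fitted porcine conductances / maxima
    g_Na: float = 13.99
    g_K1: float = 0.08218
    g_Kur_amp: float = 0.45539
    g_ClCa: float = 0.15731
    g_Kr: float = 0.0173
    g_Ks: float = 0.0594
    g_CaL: float = 0.06574
    I_NaK_max: float = 0.94935
    I_NaCa_max: float = 2304.0

    # retained from the source formulations
    g_bNa: float = 0.0006744375
    g_bCa: float = 0.001131
    I_pCa_max: float = 0.275

    C_m: float = 100.0
    T: float = BODY_TEMPERATURE
    Na_o: float = 140.0
    K_o: float = 5.4
    Ca_o: float = 1.8
    #: fixed Cl- reversal potential (Nernst at 310.15 K, 29.26/132 mM)
    E_Cl: float = -40.2640

    # porcine kinetic adjustments
    tau_m_scale: float = 1.7
    tau_h_scale: float = 2.0
    tau_j_scale: float = 2.0
    a_Kur: float = 0.25
    b_Kur: float = 0.75
    tau_uis_factor: float = 20.0
    #: mV shift of the d-gate half-points (positive = toward positive V);
    #: the porcine adjustment shifts the activation time constant by +5 mV
    d_inf_shift: float = 0.0
    d_tau_shift: float = 5.0
    xr_half: float = 4.4451
    xr_slope: float = 9.3305
    kr_rect_half: float = 79.4825
    kr_rect_slope: float = 8.2217
    p1: float = 18.802
    p2: float = 12.6475
    xs_alpha_coeff: float = 4.0e-5
    fca_half: float = 0.00035
    qca_fn_half: float = 1.1e-10
    rel_inact_shift: float = 40.0
    rel_inact_slope: float = 8.5

    # SR transport and buffers
    I_up_max: float = 0.005
    K_up: float = 0.00092
    Ca_up_max: float = 15.0
    k_rel: float = 30.0
    tau_tr: float = 180.0
    Km_Nai: float = 10.0
    Km_Ko: float = 1.5
    Km_Na: float = 87.5
    Km_Ca: float = 1.38
    k_sat: float = 0.1
    gamma_NaCa: float = 0.35
    cmdn_max: float = 0.05
    trpn_max: float = 0.07
    csqn_max: float = 10.0
    Km_cmdn: float = 0.00238
    Km_trpn: float = 0.0005
    Km_csqn: float = 0.8

    # cell compartment volumes, um^3
    V_i: float = 13668.0
    V_up: float = 1109.52
    V_rel: float = 96.48

    K_Q10: float = 3.0

    #: tissue diffusion coefficient, cm^2/ms
    D: float = 0.00126

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        positive = (
            "g_Na", "g_K1", "g_Kur_amp", "g_ClCa", "g_Kr", "g_Ks", "g_CaL",
            "g_bNa", "g_bCa", "I_NaK_max", "I_NaCa_max", "I_pCa_max", "C_m",
            "T", "Na_o", "K_o", "Ca_o", "I_up_max", "k_rel", "D",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if not math.isclose(self.a_Kur + self.b_Kur, 1.0, abs_tol=1e-12):
            raise ValueError("I_Kur inactivation weights must satisfy a + b = 1")

    # -- conversions ---------------------------------------------------------
    @property
    def RT_over_F(self) -> float:
        return R_GAS * self.T / FARADAY

    def stimulus_per_pF(self, amplitude_nA: float) -> float:
        """Convert a whole-cell stimulus in nA to pA/pF via C_m."""
        return amplitude_nA * 1000.0 / self.C_m

    def pack(self) -> np.ndarray:
        """Flatten into the parameter vector consumed by the kernel."""
        p = np.empty(L.NPAR, dtype=np.float64)
        p[L.PG_NA] = self.g_Na
        p[L.PG_K1] = self.g_K1
        p[L.PG_KUR_AMP] = self.g_Kur_amp
        p[L.PG_CLCA] = self.g_ClCa
        p[L.PG_KR] = self.g_Kr
        p[L.PG_KS] = self.g_Ks
        p[L.PG_CAL] = self.g_CaL
        p[L.PG_BNA] = self.g_bNa
        p[L.PG_BCA] = self.g_bCa
        p[L.PI_NAK_MAX] = self.I_NaK_max
        p[L.PI_NACA_MAX] = self.I_NaCa_max
        p[L.PI_PCA_MAX] = self.I_pCa_max
        p[L.PCM] = self.C_m
        p[L.PTEMP] = self.T
        p[L.PNA_O] = self.Na_o
        p[L.PK_O] = self.K_o
        p[L.PCA_O] = self.Ca_o
        p[L.PE_CL] = self.E_Cl
        p[L.PTAU_M_SCALE] = self.tau_m_scale
        p[L.PTAU_H_SCALE] = self.tau_h_scale
        p[L.PTAU_J_SCALE] = self.tau_j_scale
        p[L.PA_KUR] = self.a_Kur
        p[L.PB_KUR] = self.b_Kur
        p[L.PTAU_UIS_FACTOR] = self.tau_uis_factor
        p[L.PD_INF_SHIFT] = self.d_inf_shift
        p[L.PD_TAU_SHIFT] = self.d_tau_shift
        p[L.PXR_HALF] = self.xr_half
        p[L.PXR_SLOPE] = self.xr_slope
        p[L.PKR_RECT_HALF] = self.kr_rect_half
        p[L.PKR_RECT_SLOPE] = self.kr_rect_slope
        p[L.PP1] = self.p1
        p[L.PP2] = self.p2
        p[L.PXS_ALPHA] = self.xs_alpha_coeff
        p[L.PFCA_HALF] = self.fca_half
        p[L.PQCA_FN_HALF] = self.qca_fn_half
        p[L.PREL_INACT_SHIFT] = self.rel_inact_shift
        p[L.PREL_INACT_SLOPE] = self.rel_inact_slope
        p[L.PI_UP_MAX] = self.I_up_max
        p[L.PK_UP] = self.K_up
        p[L.PCA_UP_MAX] = self.Ca_up_max
        p[L.PK_REL] = self.k_rel
        p[L.PTAU_TR] = self.tau_tr
        p[L.PKM_NAI] = self.Km_Nai
        p[L.PKM_KO] = self.Km_Ko
        p[L.PKM_NA] = self.Km_Na
        p[L.PKM_CA] = self.Km_Ca
        p[L.PK_SAT] = self.k_sat
        p[L.PGAMMA] = self.gamma_NaCa
        p[L.PCMDN_MAX] = self.cmdn_max
        p[L.PTRPN_MAX] = self.trpn_max
        p[L.PCSQN_MAX] = self.csqn_max
        p[L.PKM_CMDN] = self.Km_cmdn
        p[L.PKM_TRPN] = self.Km_trpn
        p[L.PKM_CSQN] = self.Km_csqn
        p[L.PV_I] = self.V_i
        p[L.PV_UP] = self.V_up
        p[L.PV_REL] = self.V_rel
        p[L.PK_Q10] = self.K_Q10
        p[L.PDIFF] = self.D
        return p

    # -- (de)serialisation ---------------------------------------------------
    def replace(self, **overrides: float) -> "ModelParameters":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        unknown = set(overrides) - set(values)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        values.update(overrides)
        return ModelParameters(**values)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        return cls().replace(**mapping)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("parameters", {}))


DEFAULT_PARAMETERS = ModelParameters()
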