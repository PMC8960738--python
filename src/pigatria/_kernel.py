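"""Numerical kernel: gate kinetics, membrane currents and the explicit
time-stepper, written as scalar loops over cells.

Everything here is plain arithmetic on flat arrays so the same source runs
either jitted by numba (the default) or as pure Python (fallback when numba
is unavailable).  The public, documented API lives in
:mod:`pigatria.ionic_model`; this module is internal.

Conventions
-----------
* voltages mV, time ms, concentrations mM, membrane currents pA/pF,
  SR fluxes mM/ms.
* ``dvdt_extra`` is an additive contribution to dV/dt in mV/ms; stimulus
  (positive = depolarising) and the diffusion term both enter through it.
* The myoplasmic Ca2+ flux F_n follows the classic trigger-flux bookkeeping
  expression (release-compartment volume times SR release flux minus the
  L-type/exchanger trigger term with total-cell currents in pA).
"""

import math

import numpy as np

from ._layout import (  # noqa: F401
    IV, IM, IH, IJ, ID, IF, IFCA, IUA, IUIF, IUIS, IXR, IXS, IQCA,
    IU, IVG, IW, INAI, IKI, ICAI, ICAUP, ICAREL, NVAR,
    PG_NA, PG_K1, PG_KUR_AMP, PG_CLCA, PG_KR, PG_KS, PG_CAL, PG_BNA, PG_BCA,
    PI_NAK_MAX, PI_NACA_MAX, PI_PCA_MAX, PCM, PTEMP, PNA_O, PK_O, PCA_O,
    PE_CL, PTAU_M_SCALE, PTAU_H_SCALE, PTAU_J_SCALE, PA_KUR, PB_KUR,
    PTAU_UIS_FACTOR, PD_INF_SHIFT, PD_TAU_SHIFT, PXR_HALF, PXR_SLOPE,
    PKR_RECT_HALF, PKR_RECT_SLOPE, PP1, PP2, PXS_ALPHA, PFCA_HALF,
    PQCA_FN_HALF,
    PREL_INACT_SHIFT, PREL_INACT_SLOPE, PI_UP_MAX, PK_UP, PCA_UP_MAX,
    PK_REL, PTAU_TR, PKM_NAI, PKM_KO, PKM_NA, PKM_CA, PK_SAT, PGAMMA,
    PCMDN_MAX, PTRPN_MAX, PCSQN_MAX, PKM_CMDN, PKM_TRPN, PKM_CSQN,
    PV_I, PV_UP, PV_REL, PK_Q10,
    CI_NA, CI_K1, CI_CLCA, CI_KUR, CI_KR, CI_KS, CI_CAL, CI_PCA, CI_NAK,
    CI_NACA, CI_BNA, CI_BCA, CI_UP, CI_REL, CI_TR, CI_UP_LEAK, CI_FN,
    CI_ION, NCUR,
)
from .constants import R_GAS, FARADAY

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


_EPS = 1.0e-6


@njit(cache=False)
def _sodium_gates(v, p):
    """Steady states and time constants of m, h, j (the classic
    guinea-pig-ventricle rate functions, time constants rescaled for the
    slower porcine upstroke)."""
    dv = v + 47.13
    if abs(dv) < _EPS:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-v / 11.0)
    m_inf = am / (am + bm)
    tau_m = p[PTAU_M_SCALE] / (am + bm)

    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * math.exp(-(v + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = ((-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    h_inf = ah / (ah + bh)
    tau_h = p[PTAU_H_SCALE] / (ah + bh)
    j_inf = aj / (aj + bj)
    tau_j = p[PTAU_J_SCALE] / (aj + bj)
    return m_inf, tau_m, h_inf, tau_h, j_inf, tau_j


@njit(cache=False)
def _ical_gates(v, p):
    """d and f gates.  The half-points of the d-gate steady state and time
    constant can be shifted independently (mV, positive = rightward)."""
    vd = v - p[PD_INF_SHIFT]
    d_inf = 1.0 / (1.0 + math.exp(-(vd + 10.0) / 8.0))
    dvd = v - p[PD_TAU_SHIFT] + 10.0
    e = math.exp(-dvd / 6.24)
    if abs(dvd) < _EPS:
        tau_d = (1.0 / 6.24) / (0.035 * 2.0)
    else:
        tau_d = (1.0 - e) / (0.035 * dvd * (1.0 + e))
    f_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    return d_inf, tau_d, f_inf, tau_f


@njit(cache=False)
def _kur_gates(v, p):
    """u_a activation plus the shared steady state of the bi-exponential
    inactivation; the slow component relaxes a fixed factor slower."""
    q10 = p[PK_Q10]
    aa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    ba = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    ua_inf = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    tau_ua = 1.0 / ((aa + ba) * q10)

    ai = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    bi = math.exp((v - 158.0) / 16.0)
    ui_inf = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))
    tau_uif = 1.0 / ((ai + bi) * q10)
    tau_uis = tau_uif * p[PTAU_UIS_FACTOR]
    return ua_inf, tau_ua, ui_inf, tau_uif, tau_uis


@njit(cache=False)
def _xr_gate(v, p):
    dv1 = v + 14.1
    if abs(dv1) < _EPS:
        a = 0.0003 * 5.0
    else:
        a = 0.0003 * dv1 / (1.0 - math.exp(-dv1 / 5.0))
    dv2 = v - 3.3328
    if abs(dv2) < _EPS:
        b = 7.3898e-5 * 5.1237
    else:
        b = 7.3898e-5 * dv2 / (math.exp(dv2 / 5.1237) - 1.0)
    tau = 1.0 / (a + b)
    inf = 1.0 / (1.0 + math.exp(-(v - p[PXR_HALF]) / p[PXR_SLOPE]))
    return inf, tau


@njit(cache=False)
def _xs_gate(v, p):
    dv = v - p[PP1]
    if abs(dv) < _EPS:
        a = p[PXS_ALPHA] * 17.0
        b = 3.5e-5 * 9.0
    else:
        a = p[PXS_ALPHA] * dv / (1.0 - math.exp(-dv / 17.0))
        b = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    tau = 0.5 / (a + b)
    inf = math.sqrt(1.0 / (1.0 + math.exp(-dv / p[PP2])))
    return inf, tau


@njit(cache=False)
def _w_gate(v, p):
    half = 40.0 + p[PREL_INACT_SHIFT]
    inf = 1.0 - 1.0 / (1.0 + math.exp(-(v - half) / p[PREL_INACT_SLOPE]))
    dv = v - 7.9
    if abs(dv) < _EPS:
        tau = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-dv / 5.0)
        tau = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)
    return inf, tau


@njit(cache=False)
def _fca_gate(cai, p):
    return 1.0 / (1.0 + cai / p[PFCA_HALF]), 2.0


@njit(cache=False)
def _fn_gates(fn, v, p):
    """Gates driven by the myoplasmic Ca2+ flux: SR release activation u,
    flux inactivation v, and the I_ClCa gate q_Ca."""
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    x = fn / p[PQCA_FN_HALF]
    if x < 0.0:
        x = 0.0
    qca_inf = 1.0 - 1.0 / (1.0 + x * x * x)
    return u_inf, 8.0, v_inf, tau_v, qca_inf, 2.0


@njit(cache=False)
def _currents_point(v, m, h, j, d, f, fca, ua, uif, uis, xr, xs, qca,
                    u, vg, w, nai, ki, cai, caup, carel, p):
    """All membrane currents (pA/pF), SR fluxes (mM/ms) and F_n for one cell."""
    rtf = R_GAS * p[PTEMP] / FARADAY
    e_na = rtf * math.log(p[PNA_O] / nai)
    e_k = rtf * math.log(p[PK_O] / ki)
    e_ca = 0.5 * rtf * math.log(p[PCA_O] / cai)

    i_na = p[PG_NA] * m * m * m * h * j * (v - e_na)
    i_k1 = p[PG_K1] * (v - e_k - 5.0) / (1.0 + math.exp(0.063 * (v + 70.0)))
    i_clca = p[PG_CLCA] * qca * (v - p[PE_CL])
    g_kur = p[PG_KUR_AMP] * (0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0)))
    i_kur = g_kur * ua * ua * ua * (p[PA_KUR] * uif + p[PB_KUR] * uis) * (v - e_k)
    i_kr = (p[PG_KR] * xr * (v - e_k)
            / (1.0 + math.exp((v - p[PKR_RECT_HALF]) / p[PKR_RECT_SLOPE])))
    i_ks = p[PG_KS] * xs * xs * (v - e_k)
    i_cal = p[PG_CAL] * d * f * fca * (v - 65.0)
    i_pca = p[PI_PCA_MAX] * cai / (0.0005 + cai)

    vff = v * FARADAY / (R_GAS * p[PTEMP])
    sigma = (math.exp(p[PNA_O] / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vff) + 0.0365 * sigma * math.exp(-vff))
    i_nak = (p[PI_NAK_MAX] * f_nak * p[PK_O]
             / ((1.0 + (p[PKM_NAI] / nai) ** 1.5) * (p[PK_O] + p[PKM_KO])))

    eg = math.exp(p[PGAMMA] * vff)
    eg1 = math.exp((p[PGAMMA] - 1.0) * vff)
    i_naca = (p[PI_NACA_MAX]
              * (eg * nai ** 3 * p[PCA_O] - eg1 * p[PNA_O] ** 3 * cai)
              / ((p[PKM_NA] ** 3 + p[PNA_O] ** 3) * (p[PKM_CA] + p[PCA_O])
                 * (1.0 + p[PK_SAT] * eg1)))

    i_bna = p[PG_BNA] * (v - e_na)
    i_bca = p[PG_BCA] * (v - e_ca)

    i_ion = (i_na + i_k1 + i_clca + i_kur + i_kr + i_ks + i_cal
             + i_pca + i_nak + i_naca + i_bna + i_bca)

    i_rel = p[PK_REL] * u * u * vg * w * (carel - cai)
    i_tr = (caup - carel) / p[PTAU_TR]
    i_up = p[PI_UP_MAX] / (1.0 + p[PK_UP] / cai)
    i_up_leak = p[PI_UP_MAX] * caup / p[PCA_UP_MAX]

    fn = (1.0e-12 * p[PV_REL] * i_rel
          - (5.0e-13 / FARADAY) * (0.5 * i_cal - 0.2 * i_naca) * p[PCM])

    return (i_na, i_k1, i_clca, i_kur, i_kr, i_ks, i_cal, i_pca, i_nak,
            i_naca, i_bna, i_bca, i_up, i_rel, i_tr, i_up_leak, fn, i_ion)


@njit(cache=False)
def currents_cells(S, p, out):
    """Fill ``out`` (NCUR, n) with currents for every column of ``S``."""
    n = S.shape[1]
    for i in range(n):
        cur = _currents_point(
            S[IV, i], S[IM, i], S[IH, i], S[IJ, i], S[ID, i], S[IF, i],
            S[IFCA, i], S[IUA, i], S[IUIF, i], S[IUIS, i], S[IXR, i],
            S[IXS, i], S[IQCA, i], S[IU, i], S[IVG, i], S[IW, i],
            S[INAI, i], S[IKI, i], S[ICAI, i], S[ICAUP, i], S[ICAREL, i], p)
        for k in range(NCUR):
            out[k, i] = cur[k]


@njit(cache=False)
def _advance_gate(g, inf, tau, dt, rush_larsen):
    if rush_larsen:
        return inf + (g - inf) * math.exp(-dt / tau)
    return g + dt * (inf - g) / tau


@njit(cache=False)
def step_cells(S, dvdt_extra, dt, p, rush_larsen, clamp_v, clamp_cai,
               dynamic_ions):
    """Advance every cell by one forward-Euler step of length ``dt``.

    ``dvdt_extra`` holds per-cell additive dV/dt terms (stimulus + diffusion).
    Gate update is forward Euler by default, exponential (Rush-Larsen) when
    requested.  Flags are ints (0/1).
    """
    n = S.shape[1]
    cm = p[PCM]
    fvi = FARADAY * p[PV_I]
    for i in range(n):
        v = S[IV, i]
        m = S[IM, i]
        h = S[IH, i]
        j = S[IJ, i]
        d = S[ID, i]
        f = S[IF, i]
        fca = S[IFCA, i]
        ua = S[IUA, i]
        uif = S[IUIF, i]
        uis = S[IUIS, i]
        xr = S[IXR, i]
        xs = S[IXS, i]
        qca = S[IQCA, i]
        u = S[IU, i]
        vg = S[IVG, i]
        w = S[IW, i]
        nai = S[INAI, i]
        ki = S[IKI, i]
        cai = S[ICAI, i]
        caup = S[ICAUP, i]
        carel = S[ICAREL, i]

        cur = _currents_point(v, m, h, j, d, f, fca, ua, uif, uis, xr, xs,
                              qca, u, vg, w, nai, ki, cai, caup, carel, p)
        i_na = cur[CI_NA]
        i_k1 = cur[CI_K1]
        i_clca = cur[CI_CLCA]
        i_kur = cur[CI_KUR]
        i_kr = cur[CI_KR]
        i_ks = cur[CI_KS]
        i_cal = cur[CI_CAL]
        i_pca = cur[CI_PCA]
        i_nak = cur[CI_NAK]
        i_naca = cur[CI_NACA]
        i_bna = cur[CI_BNA]
        i_bca = cur[CI_BCA]
        i_up = cur[CI_UP]
        i_rel = cur[CI_REL]
        i_tr = cur[CI_TR]
        i_up_leak = cur[CI_UP_LEAK]
        fn = cur[CI_FN]
        i_ion = cur[CI_ION]

        # gate targets
        m_inf, tau_m, h_inf, tau_h, j_inf, tau_j = _sodium_gates(v, p)
        d_inf, tau_d, f_inf, tau_f = _ical_gates(v, p)
        ua_inf, tau_ua, ui_inf, tau_uif, tau_uis = _kur_gates(v, p)
        xr_inf, tau_xr = _xr_gate(v, p)
        xs_inf, tau_xs = _xs_gate(v, p)
        w_inf, tau_w = _w_gate(v, p)
        fca_inf, tau_fca = _fca_gate(cai, p)
        u_inf, tau_u, v_inf, tau_v, qca_inf, tau_qca = _fn_gates(fn, v, p)

        S[IM, i] = _advance_gate(m, m_inf, tau_m, dt, rush_larsen)
        S[IH, i] = _advance_gate(h, h_inf, tau_h, dt, rush_larsen)
        S[IJ, i] = _advance_gate(j, j_inf, tau_j, dt, rush_larsen)
        S[ID, i] = _advance_gate(d, d_inf, tau_d, dt, rush_larsen)
        S[IF, i] = _advance_gate(f, f_inf, tau_f, dt, rush_larsen)
        S[IFCA, i] = _advance_gate(fca, fca_inf, tau_fca, dt, rush_larsen)
        S[IUA, i] = _advance_gate(ua, ua_inf, tau_ua, dt, rush_larsen)
        S[IUIF, i] = _advance_gate(uif, ui_inf, tau_uif, dt, rush_larsen)
        S[IUIS, i] = _advance_gate(uis, ui_inf, tau_uis, dt, rush_larsen)
        S[IXR, i] = _advance_gate(xr, xr_inf, tau_xr, dt, rush_larsen)
        S[IXS, i] = _advance_gate(xs, xs_inf, tau_xs, dt, rush_larsen)
        S[IQCA, i] = _advance_gate(qca, qca_inf, tau_qca, dt, rush_larsen)
        S[IU, i] = _advance_gate(u, u_inf, tau_u, dt, rush_larsen)
        S[IVG, i] = _advance_gate(vg, v_inf, tau_v, dt, rush_larsen)
        S[IW, i] = _advance_gate(w, w_inf, tau_w, dt, rush_larsen)

        if dynamic_ions:
            S[INAI, i] = nai + dt * cm * (-3.0 * i_nak - 3.0 * i_naca
                                          - i_bna - i_na) / fvi
            S[IKI, i] = ki + dt * cm * (2.0 * i_nak - i_k1 - i_kur
                                        - i_kr - i_ks) / fvi
            if not clamp_cai:
                b1 = (cm * (2.0 * i_naca - i_pca - i_cal - i_bca)
                      / (2.0 * fvi)
                      + (p[PV_UP] * (i_up_leak - i_up) + i_rel * p[PV_REL])
                      / p[PV_I])
                b2 = (1.0
                      + p[PTRPN_MAX] * p[PKM_TRPN] / (cai + p[PKM_TRPN]) ** 2
                      + p[PCMDN_MAX] * p[PKM_CMDN] / (cai + p[PKM_CMDN]) ** 2)
                S[ICAI, i] = cai + dt * b1 / b2

        csqn_b = 1.0 + (p[PCSQN_MAX] * p[PKM_CSQN]
                        / (carel + p[PKM_CSQN]) ** 2)
        S[ICAUP, i] = caup + dt * (i_up - i_up_leak
                                   - i_tr * p[PV_REL] / p[PV_UP])
        S[ICAREL, i] = carel + dt * (i_tr - i_rel) / csqn_b

        if not clamp_v:
            S[IV, i] = v + dt * (-i_ion + dvdt_extra[i])


@njit(cache=False)
def integrate_cell(S, p, dt, istim, rush_larsen, clamp_v, clamp_cai,
                   dynamic_ions, record_every, rec):
    """Run a single cell for ``len(istim)`` steps.

    ``istim`` is the per-step stimulus (pA/pF, positive depolarising).
    Every ``record_every`` steps the full state is copied into ``rec``
    (shape (n_records, NVAR)); pass ``record_every <= 0`` to skip recording.
    Returns the number of records written.
    """
    nstep = istim.shape[0]
    extra = np.empty(1, dtype=np.float64)
    nrec = 0
    for k in range(nstep):
        if record_every > 0 and k % record_every == 0 and nrec < rec.shape[0]:
            for q in range(NVAR):
                rec[nrec, q] = S[q, 0]
            nrec += 1
        extra[0] = istim[k]
        step_cells(S, extra, dt, p, rush_larsen, clamp_v, clamp_cai,
                   dynamic_ions)
    return nrec
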