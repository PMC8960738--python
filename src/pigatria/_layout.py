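"""Index layout shared by the integration kernel and the public containers.

The dynamical state of one cell is a column of ``NVAR`` floats; model
parameters are packed into a flat vector of ``NPAR`` floats so the jitted
kernel is free of Python objects.  Keep these integers in sync with
:mod:`pigatria.parameters` and :mod:`pigatria.state` (both import from here).
"""

# ---- state vector ----------------------------------------------------------
IV = 0       # membrane potential, mV
IM = 1       # I_Na activation
IH = 2       # I_Na fast inactivation
IJ = 3       # I_Na slow inactivation
ID = 4       # I_CaL activation
IF = 5       # I_CaL voltage inactivation
IFCA = 6     # I_CaL Ca-dependent inactivation
IUA = 7      # I_Kur activation
IUIF = 8     # I_Kur fast inactivation
IUIS = 9     # I_Kur slow inactivation
IXR = 10     # I_Kr activation
IXS = 11     # I_Ks activation
IQCA = 12    # I_ClCa gate (driven by the myoplasmic Ca flux F_n)
IU = 13      # SR release activation (F_n)
IVG = 14     # SR release inactivation (F_n)
IW = 15      # SR release voltage inactivation
INAI = 16    # [Na+]_i, mM
IKI = 17     # [K+]_i, mM
ICAI = 18    # [Ca2+]_i, mM
ICAUP = 19   # [Ca2+] in uptake compartment (NSR), mM
ICAREL = 20  # [Ca2+] in release compartment (JSR), mM

NVAR = 21

STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "f_ca", "u_a", "u_if", "u_is",
    "x_r", "x_s", "q_ca", "u", "v", "w",
    "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)

GATE_INDICES = tuple(range(IM, IW + 1))

# ---- parameter vector ------------------------------------------------------
PG_NA = 0
PG_K1 = 1
PG_KUR_AMP = 2
PG_CLCA = 3
PG_KR = 4
PG_KS = 5
PG_CAL = 6
PG_BNA = 7
PG_BCA = 8
PI_NAK_MAX = 9
PI_NACA_MAX = 10
PI_PCA_MAX = 11
PCM = 12
PTEMP = 13
PNA_O = 14
PK_O = 15
PCA_O = 16
PE_CL = 17
PTAU_M_SCALE = 18
PTAU_H_SCALE = 19
PTAU_J_SCALE = 20
PA_KUR = 21
PB_KUR = 22
PTAU_UIS_FACTOR = 23
PD_INF_SHIFT = 24
PXR_HALF = 25
PXR_SLOPE = 26
PKR_RECT_HALF = 27
PKR_RECT_SLOPE = 28
PP1 = 29
PP2 = 30
PXS_ALPHA = 31
PFCA_HALF = 32
PQCA_FN_HALF = 33
PREL_INACT_SHIFT = 34
PREL_INACT_SLOPE = 35
PI_UP_MAX = 36
PK_UP = 37
PCA_UP_MAX = 38
PK_REL = 39
PTAU_TR = 40
PKM_NAI = 41
PKM_KO = 42
PKM_NA = 43
PKM_CA = 44
PK_SAT = 45
PGAMMA = 46
PCMDN_MAX = 47
PTRPN_MAX = 48
PCSQN_MAX = 49
PKM_CMDN = 50
PKM_TRPN = 51
PKM_CSQN = 52
PV_I = 53
PV_UP = 54
PV_REL = 55
PK_Q10 = 56
PDIFF = 57
PD_TAU_SHIFT = 58

NPAR = 59

# ---- current vector (outputs of the currents kernel) -----------------------
CI_NA = 0
CI_K1 = 1
CI_CLCA = 2
CI_KUR = 3
CI_KR = 4
CI_KS = 5
CI_CAL = 6
CI_PCA = 7
CI_NAK = 8
CI_NACA = 9
CI_BNA = 10
CI_BCA = 11
CI_UP = 12
CI_REL = 13
CI_TR = 14
CI_UP_LEAK = 15
CI_FN = 16
CI_ION = 17

NCUR = 18

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_ClCa", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
    "I_pCa", "I_NaK", "I_NaCa", "I_bNa", "I_bCa",
    "I_up", "I_rel", "I_tr", "I_up_leak", "F_n", "I_ion",
)
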