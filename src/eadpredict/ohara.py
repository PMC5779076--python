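"""O'Hara–Rudy (2011) endocardial human ventricular myocyte model.

The model is transcribed from the original publication's equation
supplement / reference code (endocardial parameterisation, no CiPA or
dynamic-hERG modifications).  It is expressed here as a compiled kernel that
returns, for every state variable, either a plain time derivative or — for
the 31 states whose dynamics are of the Hodgkin–Huxley form
``dy/dt = (y_inf - y) / tau`` — the pair ``(y_inf, tau)``.  The latter lets
the integrator in :mod:`eadpredict.engine` use exact exponential
(Rush–Larsen) updates for the gates while the remaining ten states
(membrane potential, six ion concentrations, SR calcium pools and the CaMK
trap fraction) are advanced explicitly.

Hooks for pharmacology and disease-state interventions:

* each maximal conductance/permeability among {I_Na, I_CaL, I_Kr, I_Ks,
  I_NaL (late/persistent Na), I_to, I_K1} is multiplied by a scale factor;
* the voltage argument of the fast sodium current's inactivation dynamics —
  the h (fast and slow) and j steady-state curves, their time constants and
  the CaMK-phosphorylated steady states — is replaced by
  ``V - shift_INa_inact``, shifting the whole inactivation process in the
  depolarised direction and mimicking Brugada-type SCN5A mutations.
  Activation (m) is untouched.

State ordering is fixed and documented in :data:`STATE_NAMES`.  Units:
time ms, voltage mV, concentrations mM, currents uA/uF.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .params import DEFAULT_PACING, ModelParameters, PacingProtocol

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)
N_STATES = len(STATE_NAMES)  # 41

#: indices of states advanced by exponential (Rush-Larsen) updates
GATE_INDICES = np.array(
    [9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23,
     24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39],
    dtype=np.int64,
)

#: Published initial conditions (the model authors' reference starting
#: state).  Long pre-pacing is still required to reach steady state at any
#: given cycle length.
INITIAL_STATE = np.array(
    [
        -87.0,   # v (mV)
        7.0,     # nai (mM)
        7.0,     # nass
        145.0,   # ki
        145.0,   # kss
        1.0e-4,  # cai
        1.0e-4,  # cass
        1.2,     # cansr
        1.2,     # cajsr
        0.0,     # m
        1.0,     # hf
        1.0,     # hs
        1.0,     # j
        1.0,     # hsp
        1.0,     # jp
        0.0,     # mL
        1.0,     # hL
        1.0,     # hLp
        0.0,     # a
        1.0,     # iF
        1.0,     # iS
        0.0,     # ap
        1.0,     # iFp
        1.0,     # iSp
        0.0,     # d
        1.0,     # ff
        1.0,     # fs
        1.0,     # fcaf
        1.0,     # fcas
        1.0,     # jca
        0.0,     # nca
        1.0,     # ffp
        1.0,     # fcafp
        0.0,     # xrf
        0.0,     # xrs
        0.0,     # xs1
        0.0,     # xs2
        1.0,     # xk1
        0.0,     # Jrelnp (mM/ms)
        0.0,     # Jrelp
        0.0,     # CaMKt
    ],
    dtype=np.float64,
)


@njit(cache=True)
def _exp_ratio(u):
    """u / (exp(u) - 1), series-expanded near the removable singularity."""
    if abs(u) < 1e-4:
        return 1.0 - 0.5 * u + u * u / 12.0
    return u / math.expm1(u)


@njit(cache=True)
def _derivatives(t, y, p, i_stim, dy, ginf, gtau):
    """Fill dy (all 41 states), and (ginf, gtau) for the RL-updated gates.

    ``p`` packs [scale_INa, scale_ICaL, scale_IKr, scale_IKs, scale_IpNa,
    scale_Ito, scale_IK1, shift_INa_inact]; ``i_stim`` is the applied
    stimulus current (uA/uF) at time ``t``.  For non-gate states gtau is set
    to -1.  Returns the membrane potential derivative (mV/ms).
    """
    # -- constants ---------------------------------------------------------
    nao = 140.0
    cao = 1.8
    ko = 5.4
    R = 8314.0
    T = 310.0
    F = 96485.0

    L = 0.01
    rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    Ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    s_na = p[0]
    s_cal = p[1]
    s_kr = p[2]
    s_ks = p[3]
    s_nal = p[4]
    s_to = p[5]
    s_k1 = p[6]
    shift = p[7]

    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    jg = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]

    # -- CaMK --------------------------------------------------------------
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
    fcamk = 1.0 / (1.0 + KmCaMK / CaMKa)

    # -- reversal potentials ----------------------------------------------
    ENa = (R * T / F) * math.log(nao / nai)
    EK = (R * T / F) * math.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * math.log((ko + PKNa * nao) / (ki + PKNa * nai))

    vfrt = v * F / (R * T)

    # -- I_Na (fast sodium) ------------------------------------------------
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (
        6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955)
    )
    ginf[9] = mss
    gtau[9] = tm

    vh = v - shift  # inactivation curves shifted in the depolarised direction
    hss = 1.0 / (1.0 + math.exp((vh + 82.90) / 6.086))
    thf = 1.0 / (
        1.432e-5 * math.exp(-(vh + 1.196) / 6.285) + 6.149 * math.exp((vh + 0.5096) / 20.27)
    )
    ths = 1.0 / (
        0.009794 * math.exp(-(vh + 17.95) / 28.05) + 0.3343 * math.exp((vh + 5.730) / 56.66)
    )
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    ginf[10] = hss
    gtau[10] = thf
    ginf[11] = hss
    gtau[11] = ths
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (
        0.02136 * math.exp(-(vh + 100.6) / 8.281) + 0.3052 * math.exp((vh + 0.9941) / 38.45)
    )
    ginf[12] = jss
    gtau[12] = tj
    hssp = 1.0 / (1.0 + math.exp((vh + 89.1) / 6.086))
    thsp = 3.0 * ths
    ginf[13] = hssp
    gtau[13] = thsp
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    ginf[14] = jss
    gtau[14] = tjp
    GNa = 75.0 * s_na
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fcamk) * h * jg + fcamk * hp * jp)

    # -- I_NaL (late/persistent sodium) -------------------------------------
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    ginf[15] = mLss
    gtau[15] = tmL
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    ginf[16] = hLss
    gtau[16] = thL
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    ginf[17] = hLssp
    gtau[17] = thLp
    GNaL = 0.0075 * s_nal
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fcamk) * hL + fcamk * hLp)

    # -- I_to ---------------------------------------------------------------
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    ginf[18] = ass
    gtau[18] = ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    # endocardial cell: delta_epi = 1
    tiF = 4.562 + 1.0 / (
        0.3933 * math.exp(-(v + 100.0) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59)
    )
    tiS = 23.62 + 1.0 / (
        0.001416 * math.exp(-(v + 96.52) / 59.05) + 1.780e-8 * math.exp((v + 114.1) / 8.079)
    )
    ginf[19] = iss
    gtau[19] = tiF
    ginf[20] = iss
    gtau[20] = tiS
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    ginf[21] = assp
    gtau[21] = ta
    dti_develop = 1.354 + 1.0e-4 / (
        math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154)
    )
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ginf[22] = iss
    gtau[22] = tiFp
    ginf[23] = iss
    gtau[23] = tiSp
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02 * s_to
    Ito = Gto * (v - EK) * ((1.0 - fcamk) * a * i_gate + fcamk * ap * ip)

    # -- I_CaL / I_CaNa / I_CaK --------------------------------------------
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    ginf[24] = dss
    gtau[24] = td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (
        0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0)
    )
    tfs = 1000.0 + 1.0 / (
        0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0)
    )
    Aff = 0.6
    Afs = 1.0 - Aff
    ginf[25] = fss
    gtau[25] = tff
    ginf[26] = fss
    gtau[26] = tfs
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (
        0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0)
    )
    tfcas = 100.0 + 1.0 / (
        0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0)
    )
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    ginf[27] = fcass
    gtau[27] = tfcaf
    ginf[28] = fcass
    gtau[28] = tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    ginf[29] = fcass
    gtau[29] = tjca
    tffp = 2.5 * tff
    ginf[31] = fss
    gtau[31] = tffp
    fp = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    ginf[32] = fcass
    gtau[32] = tfcafp
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # dnca = anca*k2n - nca*km2n, linear in nca -> treat as a gate
    ginf[30] = anca * k2n / km2n
    gtau[30] = 1.0 / km2n

    u2 = 2.0 * vfrt
    PhiCaL = 2.0 * F * (cass * math.exp(u2) - 0.341 * cao) * _exp_ratio(u2)
    PhiCaNa = F * (0.75 * nass * math.exp(vfrt) - 0.75 * nao) * _exp_ratio(vfrt)
    PhiCaK = F * (0.75 * kss * math.exp(vfrt) - 0.75 * ko) * _exp_ratio(vfrt)
    PCa = 0.0001 * s_cal
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fcamk) * PCa * PhiCaL * gate_np + fcamk * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fcamk) * PCaNa * PhiCaNa * gate_np + fcamk * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fcamk) * PCaK * PhiCaK * gate_np + fcamk * PCaKp * PhiCaK * gate_p

    # -- I_Kr ---------------------------------------------------------------
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (
        0.3652 * math.exp((v - 31.66) / 3.869) + 4.123e-5 * math.exp(-(v - 47.78) / 20.38)
    )
    txrs = 1.865 + 1.0 / (
        0.06629 * math.exp((v - 34.70) / 7.355) + 1.128e-5 * math.exp(-(v - 29.74) / 25.94)
    )
    ginf[33] = xrss
    gtau[33] = txrf
    ginf[34] = xrss
    gtau[34] = txrs
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))) * (
        1.0 / (1.0 + math.exp((v - 10.0) / 30.0))
    )
    GKr = 0.046 * s_kr
    IKr = GKr * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # -- I_Ks ---------------------------------------------------------------
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (
        2.326e-4 * math.exp((v + 48.28) / 17.80) + 0.001292 * math.exp(-(v + 210.0) / 230.0)
    )
    ginf[35] = xs1ss
    gtau[35] = txs1
    xs2ss = xs1ss
    txs2 = 1.0 / (
        0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0)
    )
    ginf[36] = xs2ss
    gtau[36] = txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * s_ks
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # -- I_K1 ---------------------------------------------------------------
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    ginf[37] = xk1ss
    gtau[37] = txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908 * s_k1
    IK1 = GK1 * math.sqrt(ko) * rk1 * xk1 * (v - EK)

    # -- I_NaCa (myoplasmic and subspace components) -------------------------
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    KmCaAct = 150.0e-6
    zna = 1.0
    zca = 2.0
    Gncx = 0.0008

    # myoplasmic
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p_ = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p_ + k3pp
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k6 = h6 * cass * kcaon
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # -- I_NaK ---------------------------------------------------------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3) / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    a3 = (k3p_ * (ko / Kko) ** 2) / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p_ * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # -- background / minor currents ----------------------------------------
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * F * (nai * math.exp(vfrt) - nao) * _exp_ratio(vfrt)
    PCab = 2.5e-8
    ICab = PCab * 2.0 * F * (cai * math.exp(u2) - 0.341 * cao) * _exp_ratio(u2)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # -- diffusion fluxes ----------------------------------------------------
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # -- SR calcium release (RyR), treated as gated fluxes -------------------
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    ginf[38] = Jrel_inf
    gtau[38] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    ginf[39] = Jrel_infp
    gtau[39] = tau_relp
    Jrel = (1.0 - fcamk) * Jrelnp + fcamk * Jrelp

    # -- SERCA uptake / leak / translocation ---------------------------------
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fcamk) * Jupnp + fcamk * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # -- membrane potential ---------------------------------------------------
    I_total = (
        INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
        + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + i_stim
    )
    dy[0] = -I_total

    # -- ionic concentrations -------------------------------------------------
    dy[1] = (
        -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * Acap / (F * vmyo)
        + JdiffNa * vss / vmyo
    )
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    dy[3] = (
        -(Ito + IKr + IKs + IK1 + IKb + i_stim - 2.0 * INaK) * Acap / (F * vmyo)
        + JdiffK * vss / vmyo
    )
    dy[4] = -ICaK * Acap / (F * vss) - JdiffK

    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    Bcai = 1.0 / (
        1.0
        + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
        + trpnmax * kmtrpn / (kmtrpn + cai) ** 2
    )
    dy[5] = Bcai * (
        -(IpCa + ICab - 2.0 * INaCa_i) * Acap / (2.0 * F * vmyo)
        - Jup * vnsr / vmyo
        + Jdiff * vss / vmyo
    )
    Bcass = 1.0 / (
        1.0
        + BSRmax * KmBSR / (KmBSR + cass) ** 2
        + BSLmax * KmBSL / (KmBSL + cass) ** 2
    )
    dy[6] = Bcass * (
        -(ICaL - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss) + Jrel * vjsr / vss - Jdiff
    )
    dy[7] = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    # gate derivatives (for callers wanting a plain ODE right-hand side)
    for gi in range(9, 40):
        dy[gi] = (ginf[gi] - y[gi]) / gtau[gi]

    return dy[0]


@njit(cache=True)
def _stimulus_current(t, stim):
    """Applied current (uA/uF) at time t for stim=[amp, dur, period, offset]."""
    phase = (t - stim[3]) % stim[2]
    if 0.0 <= phase < stim[1]:
        return stim[0]
    return 0.0


@njit(cache=True)
def _rhs_flat(t, y, p, stim):
    dy = np.empty(N_STATES)
    ginf = np.empty(N_STATES)
    gtau = np.empty(N_STATES)
    _derivatives(t, y, p, _stimulus_current(t, stim), dy, ginf, gtau)
    return dy


def rhs(
    state: np.ndarray,
    t: float,
    params: ModelParameters | None = None,
    pacing: PacingProtocol | None = None,
) -> np.ndarray:
    """Time derivative of the full state vector at time ``t``.

    The stimulus current implied by ``pacing`` is included.  Raises on
    non-finite state entries, naming the offending variable.
    """
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have length {N_STATES}, got shape {state.shape}")
    bad = ~np.isfinite(state)
    if bad.any():
        names = [STATE_NAMES[k] for k in np.flatnonzero(bad)]
        raise ValueError(f"non-finite state entries: {', '.join(names)}")
    if t < 0:
        raise ValueError("t must be >= 0")
    params = params or ModelParameters()
    pacing = pacing or DEFAULT_PACING
    return _rhs_flat(t, state, params.as_array(), pacing.as_array())


def h_inf(v: np.ndarray | float, params: ModelParameters | None = None):
    """Steady-state fast inactivation curve h_inf(V) with the shift applied."""
    shift = (params or ModelParameters()).shift_INa_inact
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - shift + 82.90) / 6.086))


def inactivation_midpoint(params: ModelParameters | None = None) -> float:
    """Voltage (mV) at which the shifted h_inf curve crosses 0.5.

    Root-found to |dV| < 1e-6 mV; mainly a diagnostic/testing hook for the
    inactivation-shift intervention.
    """
    params = params or ModelParameters()
    lo = -200.0 + params.shift_INa_inact
    hi = 100.0 + params.shift_INa_inact
    return float(brentq(lambda v: h_inf(v, params) - 0.5, lo, hi, xtol=1e-9))
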