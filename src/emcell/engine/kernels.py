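"""Compiled right-hand sides and the fixed-schedule integrator.

The derivative kernels below are a second, flattened transcription of
the model equations (the readable reference lives in
``emcell.ep.reference`` and ``emcell.land``); the two transcriptions are
compared term by term in the test suite.

Time stepping is a deterministic hybrid scheme: Hodgkin-Huxley-type
gates (and other states with ``(x_inf - x)/tau`` form) are advanced with
the exponential Rush-Larsen update, everything else with forward Euler.
The step size follows a fixed two-level schedule -- ``DT_FAST`` while
the membrane potential or subspace calcium move quickly, ``DT_SLOW``
otherwise -- and always lands exactly on stimulus edges and output
samples, which makes repeated runs bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# variant ids
TORORD_ID = 0
ORD_ID = 1

# physical constants
R = 8314.0
T = 310.0
F = 96485.0
RTF = R * T / F

# geometry
L_CELL = 0.01
RAD = 0.0011
VCELL = 1000.0 * 3.14 * RAD * RAD * L_CELL
AGEO = 2.0 * 3.14 * RAD * RAD + 2.0 * 3.14 * RAD * L_CELL
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

TRPNMAX = 0.07  # mM, total troponin C; also the coupling feedback concentration

# packed-parameter indices (mirror emcell.ep.params.P)
(GNA, GNAL, GTO, PCA, GKR, GKS, GK1, GNCX, PNAK, GKB,
 PNAB, PCAB, GPCA, GCLCA, GCLB,
 JREL_B, JUP_B, CMDNMAX, DELTA_EPI, JREL_INF_SC,
 NAO, CAO, KO, CLO, CLI) = range(25)

# drug-scale indices (mirror emcell.ep.params.CURRENTS)
(S_INA, S_INAL, S_ITO, S_ICAL, S_IKR, S_IKS, S_IK1,
 S_INACA, S_INAK, S_IKB, S_INAB, S_ICAB, S_IPCA, S_ICLCA, S_ICLB) = range(15)

# mech packed indices (mirror emcell.land.pack_mech_params)
(M_TREF, M_CA50, M_NTRPN, M_KTRPN, M_NTM, M_KTM, M_KTMB,
 M_KUW, M_KWS, M_KWU, M_KSU, M_ADIST, M_CDS, M_CDW,
 M_GAMS, M_GAMW, M_LFAC) = range(17)

DT_FAST = 0.005
DT_SLOW = 0.05
DV_SWITCH = 1.0        # mV/ms
DCASS_SWITCH = 0.05    # relative subspace-calcium change per ms

# default stimulus amplitudes (uA/uF) / durations (ms) per variant
STIM_DEFAULTS = {TORORD_ID: (-53.0, 1.0), ORD_ID: (-80.0, 0.5)}


@njit(cache=True)
def _camk(cass, camkt):
    camkb = 0.05 * (1.0 - camkt) / (1.0 + 0.0015 / cass)
    return camkb + camkt


@njit(cache=True)
def _phi_ghk(z, gi, ci, go, co, v):
    """GHK driving force: z^2 vF^2/RT (gi ci e^x - go co)/(e^x - 1), x = z vF/RT."""
    vffrt = v * F * F / (R * T)
    x = z * v * F / (R * T)
    num = gi * ci * np.exp(x) - go * co
    if abs(x) < 1e-7:
        return z * F * num / (1.0 + x / 2.0)
    return z * z * vffrt * num / (np.exp(x) - 1.0)


@njit(cache=True)
def _inaca_kernel(v, na, ca, nao, cao, gncx):
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    vfrt = v / RTF
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
    h1 = 1.0 + na / kna3 * (1.0 + hna)
    h2 = (na * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
    h5 = na * na / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * ca * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    tot = x1 + x2 + x3 + x4
    e1 = x1 / tot; e2 = x2 / tot; e3 = x3 / tot; e4 = x4 / tot
    allo = 1.0 / (1.0 + (150.0e-6 / ca) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    return gncx * allo * (jncxna + 2.0 * jncxca)


@njit(cache=True)
def _inak_kernel(v, nai, ki, nao, ko, pnak):
    k1p = 949.5; k1m = 182.4
    k2p = 687.2; k2m = 39.4
    k3p = 1899.0; k3m = 79300.0
    k4p = 639.0; k4m = 40.0
    vfrt = v / RTF
    knai = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
    knao = 27.78 * np.exp(1.1550 * vfrt / 3.0)
    kki = 0.5; kko = 0.3582
    mgadp = 0.05; mgatp = 9.8; kmgatp = 1.698e-7
    hconc = 1.0e-7; ep = 4.2; khp = 1.698e-7
    knap = 224.0; kxkur = 292.0
    pfrac = ep / (1.0 + hconc / khp + nai / knap + ki / kxkur)
    denom_i = (1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0
    denom_o = (1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0
    a1 = k1p * (nai / knai) ** 3 / denom_i
    b1 = k1m * mgadp
    a2 = k2p
    b2 = k2m * (nao / knao) ** 3 / denom_o
    a3 = k3p * (ko / kko) ** 2 / denom_o
    b3 = k3m * pfrac * hconc / (1.0 + mgatp / kmgatp)
    a4 = k4p * mgatp / kmgatp / (1.0 + mgatp / kmgatp)
    b4 = k4m * (ki / kki) ** 2 / denom_i
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    tot = x1 + x2 + x3 + x4
    e1 = x1 / tot; e2 = x2 / tot; e3 = x3 / tot; e4 = x4 / tot
    jnakna = 3.0 * (e1 * a3 - e2 * b3)
    jnakk = 2.0 * (e4 * b1 - e3 * a1)
    return pnak * (jnakna + jnakk)


@njit(cache=True)
def _davies(na, k, ca, cl):
    ii = 0.5 * (na + k + cl + 4.0 * ca) / 1000.0
    const_a = 1.82e6 * (74.0 * T) ** (-1.5)
    fmono = -const_a * (np.sqrt(ii) / (1.0 + np.sqrt(ii)) - 0.3 * ii)
    return np.exp(4.0 * fmono), np.exp(fmono)


@njit(cache=True)
def _land_derivs(xs, xw, catrpn, tmb, zetas, zetaw, cai_mm, mp):
    """Contraction-state derivatives; returns (dxs, dxw, dcatrpn, dtmb, dzs, dzw)."""
    ca_um = cai_mm * 1000.0
    ctr = catrpn
    if ctr < 1e-12:
        ctr = 1e-12
    elif ctr > 1.0:
        ctr = 1.0
    dcatrpn = mp[M_KTRPN] * ((ca_um / mp[M_CA50]) ** mp[M_NTRPN] * (1.0 - catrpn) - catrpn)
    xu = 1.0 - tmb - xs - xw
    perm = ctr ** (-mp[M_NTM] / 2.0)
    if perm > 100.0:
        perm = 100.0
    dtmb = mp[M_KTMB] * perm * xu - mp[M_KTM] * ctr ** (mp[M_NTM] / 2.0) * tmb
    gs = 0.0
    if zetas > 0.0:
        gs = zetas
    if zetas < -1.0 and -zetas - 1.0 > gs:
        gs = -zetas - 1.0
    grs = mp[M_GAMS] * gs
    grw = mp[M_GAMW] * abs(zetaw)
    dxs = mp[M_KWS] * xw - mp[M_KSU] * xs - grs * xs
    dxw = mp[M_KUW] * xu - mp[M_KWU] * xw - mp[M_KWS] * xw - grw * xw
    dzs = -mp[M_CDS] * zetas
    dzw = -mp[M_CDW] * zetaw
    return dxs, dxw, dcatrpn, dtmb, dzs, dzw


@njit(cache=True)
def active_tension_kernel(xs, xw, zetas, zetaw, mp):
    return mp[M_LFAC] * (mp[M_TREF] / 0.25) * ((zetas + 1.0) * xs + zetaw * xw)


@njit(cache=True)
def torord_rhs(y, p, s, istim, coupled, mp, dy, yinf, ytau):
    """ToR-ORd + Land coupled derivatives.

    Gate states receive Rush-Larsen data in (yinf, ytau); all other
    states receive forward derivatives in dy (their ytau entry is 0).
    """
    for k in range(dy.size):
        dy[k] = 0.0
        ytau[k] = 0.0
        yinf[k] = 0.0

    v = y[0]
    nai = y[1]; nass = y[2]
    ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]
    cansr = y[7]; cajsr = y[8]
    nao = p[NAO]; cao = p[CAO]; ko = p[KO]
    clo = p[CLO]; cli = p[CLI]

    ena = RTF * np.log(nao / nai)
    ek = RTF * np.log(ko / ki)
    eks = RTF * np.log((ko + 0.01833 * nao) / (ki + 0.01833 * nai))
    ecl = RTF * np.log(cli / clo)
    vfrt = v / RTF

    camkt = y[42]
    camka = _camk(cass, camkt)
    fcamk = 1.0 / (1.0 + 0.15 / camka)
    dy[42] = 0.05 * (camka - camkt) * camka - 0.00068 * camkt

    # --- INa (gates 9-13) -------------------------------------------------
    yinf[9] = 1.0 / (1.0 + np.exp(-(v + 56.86) / 9.03)) ** 2
    ytau[9] = 0.1292 * np.exp(-((v + 45.79) / 15.54) ** 2) \
        + 0.06487 * np.exp(-((v - 4.823) / 51.12) ** 2)
    hss = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
        aj = ((-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    th = 1.0 / (ah + bh)
    tj = 1.0 / (aj + bj)
    yinf[10] = hss; ytau[10] = th
    hssp = 1.0 / (1.0 + np.exp((v + 77.55) / 7.43)) ** 2
    yinf[11] = hssp; ytau[11] = th
    yinf[12] = hss; ytau[12] = tj
    yinf[13] = hss; ytau[13] = 1.46 * tj
    ina = (p[GNA] * s[S_INA] * (v - ena) * y[9] ** 3
           * ((1.0 - fcamk) * y[10] * y[12] + fcamk * y[11] * y[13]))

    # --- INaL (gates 14-16) ----------------------------------------------
    yinf[14] = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    ytau[14] = ytau[9]
    yinf[15] = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488)); ytau[15] = 200.0
    yinf[16] = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488)); ytau[16] = 600.0
    inal = (p[GNAL] * s[S_INAL] * (v - ena) * y[14]
            * ((1.0 - fcamk) * y[15] + fcamk * y[16]))

    # --- Ito (gates 17-22) -------------------------------------------------
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    yinf[17] = ass; ytau[17] = ta
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    if p[DELTA_EPI] > 0.5:
        delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tif = (4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                          + 0.08004 * np.exp((v + 50.0) / 16.59))) * delta_epi
    tis = (23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                          + 1.780e-8 * np.exp((v + 114.1) / 8.079))) * delta_epi
    yinf[18] = iss; ytau[18] = tif
    yinf[19] = iss; ytau[19] = tis
    yinf[20] = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82)); ytau[20] = ta
    dti_dev = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                + np.exp(-(v - 12.23) / 0.2154))
    dti_rec = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    yinf[21] = iss; ytau[21] = dti_dev * dti_rec * tif
    yinf[22] = iss; ytau[22] = dti_dev * dti_rec * tis
    aif = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    i_g = aif * y[18] + (1.0 - aif) * y[19]
    ip_g = aif * y[21] + (1.0 - aif) * y[22]
    ito = (p[GTO] * s[S_ITO] * (v - ek)
           * ((1.0 - fcamk) * y[17] * i_g + fcamk * y[20] * ip_g))

    # --- ICaL (gates 23-32) -------------------------------------------------
    dss = 1.0763 * np.exp(-1.0070 * np.exp(-0.0829 * v))
    if dss > 1.0:
        dss = 1.0
    yinf[23] = dss
    ytau[23] = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    yinf[24] = fss; ytau[24] = tff
    yinf[25] = fss; ytau[25] = tfs
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0) + 0.00012 * np.exp(v / 7.0))
    yinf[26] = fss; ytau[26] = tfcaf
    yinf[27] = fss; ytau[27] = tfcas
    yinf[28] = 1.0 / (1.0 + np.exp((v + 18.08) / 2.7916)); ytau[28] = 72.5
    yinf[29] = fss; ytau[29] = 2.5 * tff
    yinf[30] = fss; ytau[30] = 2.5 * tfcaf
    kmn = 0.002; k2n = 500.0
    km2n = y[28] * 1.0
    anca_ss = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    yinf[31] = anca_ss * k2n / km2n; ytau[31] = 1.0 / km2n
    anca_i = 1.0 / (k2n / km2n + (1.0 + kmn / cai) ** 4)
    yinf[32] = anca_i * k2n / km2n; ytau[32] = 1.0 / km2n

    g2ss, g1ss = _davies(nass, kss, cass, cli)
    g2i, g1i = _davies(nai, ki, cai, cli)
    g2o, g1o = _davies(nao, ko, cao, clo)
    phical_ss = _phi_ghk(2.0, g2ss, cass, g2o, cao, v)
    phicana_ss = _phi_ghk(1.0, g1ss, nass, g1o, nao, v)
    phicak_ss = _phi_ghk(1.0, g1ss, kss, g1o, ko, v)
    phical_i = _phi_ghk(2.0, g2i, cai, g2o, cao, v)
    phicana_i = _phi_ghk(1.0, g1i, nai, g1o, nao, v)
    phicak_i = _phi_ghk(1.0, g1i, ki, g1o, ko, v)
    pca = p[PCA] * s[S_ICAL]
    pcap = 1.1 * pca
    afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    f = 0.6 * y[24] + 0.4 * y[25]
    fca = afcaf * y[26] + (1.0 - afcaf) * y[27]
    f_p = 0.6 * y[29] + 0.4 * y[25]
    fcap = afcaf * y[30] + (1.0 - afcaf) * y[27]
    jca = y[28]
    op_ss = y[23] * (f * (1.0 - y[31]) + jca * fca * y[31])
    opp_ss = y[23] * (f_p * (1.0 - y[31]) + jca * fcap * y[31])
    op_i = y[23] * (f * (1.0 - y[32]) + jca * fca * y[32])
    opp_i = y[23] * (f_p * (1.0 - y[32]) + jca * fcap * y[32])
    fss_frac = 0.8
    ical_ss = ((1.0 - fcamk) * pca * phical_ss * op_ss
               + fcamk * pcap * phical_ss * opp_ss) * fss_frac
    icana_ss = ((1.0 - fcamk) * 0.00125 * pca * phicana_ss * op_ss
                + fcamk * 0.00125 * pcap * phicana_ss * opp_ss) * fss_frac
    icak_ss = ((1.0 - fcamk) * 3.574e-4 * pca * phicak_ss * op_ss
               + fcamk * 3.574e-4 * pcap * phicak_ss * opp_ss) * fss_frac
    ical_i = ((1.0 - fcamk) * pca * phical_i * op_i
              + fcamk * pcap * phical_i * opp_i) * (1.0 - fss_frac)
    icana_i = ((1.0 - fcamk) * 0.00125 * pca * phicana_i * op_i
               + fcamk * 0.00125 * pcap * phicana_i * opp_i) * (1.0 - fss_frac)
    icak_i = ((1.0 - fcamk) * 3.574e-4 * pca * phicak_i * op_i
              + fcamk * 3.574e-4 * pcap * phicak_i * opp_i) * (1.0 - fss_frac)

    # --- IKs (gates 33-34) --------------------------------------------------
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    yinf[33] = xs1ss
    ytau[33] = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                              + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    yinf[34] = xs1ss
    ytau[34] = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                      + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = p[GKS] * s[S_IKS] * ksca * y[33] * y[34] * (v - eks)

    # --- IKr Markov chain (35-39, forward Euler) ---------------------------
    alpha = 0.1161 * np.exp(0.2990 * vfrt)
    beta = 0.2442 * np.exp(-1.604 * vfrt)
    alpha1 = 0.154375
    beta1 = 0.1911
    alpha2 = 0.0578 * np.exp(0.9710 * vfrt)
    beta2 = 0.000349 * np.exp(-1.062 * vfrt)
    alphai = 0.2533 * np.exp(0.5953 * vfrt)
    betai = 0.06525 * np.exp(-0.8209 * vfrt)
    alphac2i = 5.2e-5 * np.exp(1.525 * vfrt)
    betaitoc2 = (beta2 * betai * alphac2i) / (alpha2 * alphai)
    # per-state inflow/outflow form (dy = in - out*y) so the integrator can
    # use the unconditionally stable exponential update: the closed-state
    # rates reach ~50/ms at diastolic potentials
    c0 = y[35]; c1 = y[36]; c2 = y[37]; o_ = y[38]; i_ = y[39]
    yinf[35] = c1 * beta / alpha; ytau[35] = 1.0 / alpha
    out1 = beta + alpha1
    yinf[36] = (c0 * alpha + c2 * beta1) / out1; ytau[36] = 1.0 / out1
    out2 = beta1 + alpha2 + alphac2i
    yinf[37] = (c1 * alpha1 + o_ * beta2 + i_ * betaitoc2) / out2; ytau[37] = 1.0 / out2
    outo = beta2 + alphai
    yinf[38] = (c2 * alpha2 + i_ * betai) / outo; ytau[38] = 1.0 / outo
    outi = betaitoc2 + betai
    yinf[39] = (c2 * alphac2i + o_ * alphai) / outi; ytau[39] = 1.0 / outi
    ikr = p[GKR] * s[S_IKR] * np.sqrt(ko / 5.0) * o_ * (v - ek)

    # --- IK1 (instantaneous) ------------------------------------------------
    ak1 = 4.094 / (1.0 + np.exp(0.1217 * (v - ek - 49.934)))
    bk1 = ((15.72 * np.exp(0.0674 * (v - ek - 3.257))
            + np.exp(0.0618 * (v - ek - 594.31)))
           / (1.0 + np.exp(-0.1629 * (v - ek + 14.207))))
    ik1 = p[GK1] * s[S_IK1] * np.sqrt(ko / 5.0) * ak1 / (ak1 + bk1) * (v - ek)

    # --- pumps, exchangers, background --------------------------------------
    inaca_i = 0.65 * _inaca_kernel(v, nai, cai, nao, cao, p[GNCX] * s[S_INACA])
    inaca_ss = 0.35 * _inaca_kernel(v, nass, cass, nao, cao, p[GNCX] * s[S_INACA])
    inak = _inak_kernel(v, nai, ki, nao, ko, p[PNAK] * s[S_INAK])
    xkb = 1.0 / (1.0 + np.exp(-(v - 10.8968) / 23.9871))
    ikb = p[GKB] * s[S_IKB] * xkb * (v - ek)
    inab = p[PNAB] * s[S_INAB] * _phi_ghk(1.0, 1.0, nai, 1.0, nao, v)
    icab = p[PCAB] * s[S_ICAB] * _phi_ghk(2.0, g2i, cai, g2o, cao, v)
    ipca = p[GPCA] * s[S_IPCA] * cai / (0.0005 + cai)
    iclca = p[GCLCA] * s[S_ICLCA] / (1.0 + 0.1 / cass) * (v - ecl)
    iclb = p[GCLB] * s[S_ICLB] * (v - ecl)

    # --- SR release / uptake (40-41 Rush-Larsen) ----------------------------
    bt = 4.75
    a_rel = 0.5 * bt
    jrel_inf = a_rel * (-ical_ss / fss_frac) / (1.0 + (1.7 / cajsr) ** 8) * p[JREL_INF_SC]
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    yinf[40] = jrel_inf; ytau[40] = tau_rel
    btp = 1.25 * bt
    jrel_infp = 0.5 * btp * (-ical_ss / fss_frac) / (1.0 + (1.7 / cajsr) ** 8) * p[JREL_INF_SC]
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    yinf[41] = jrel_infp; ytau[41] = tau_relp
    jrel = p[JREL_B] * ((1.0 - fcamk) * y[40] + fcamk * y[41])

    jupnp = p[JUP_B] * 0.005425 * cai / (cai + 0.00092)
    jupp = p[JUP_B] * 2.75 * 0.005425 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0048825 * cansr / 15.0
    jup = (1.0 - fcamk) * jupnp + fcamk * jupp - jleak
    jtr = (cansr - cajsr) / 60.0
    jdiff = (cass - cai) / 0.2
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0

    # --- contraction (43-48) ------------------------------------------------
    dxs, dxw, dcatrpn, dtmb, dzs, dzw = _land_derivs(
        y[43], y[44], y[45], y[46], y[47], y[48], cai, mp)
    dy[43] = dxs; dy[44] = dxw; dy[45] = dcatrpn
    dy[46] = dtmb; dy[47] = dzs; dy[48] = dzw

    # --- concentrations and membrane potential ------------------------------
    dy[1] = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab + icana_i)
             * ACAP / (F * VMYO) + jdiffna * VSS / VMYO)
    dy[2] = -(icana_ss + 3.0 * inaca_ss) * ACAP / (F * VSS) - jdiffna
    dy[3] = (-(ito + ikr + iks + ik1 + ikb + istim - 2.0 * inak + icak_i)
             * ACAP / (F * VMYO) + jdiffk * VSS / VMYO)
    dy[4] = -icak_ss * ACAP / (F * VSS) - jdiffk

    kmcmdn = 0.00238; kmtrpn = 0.0005
    if coupled == 1:
        bcai = 1.0 / (1.0 + p[CMDNMAX] * kmcmdn / (kmcmdn + cai) ** 2)
        jtrpn = dcatrpn * TRPNMAX
    else:
        bcai = 1.0 / (1.0 + p[CMDNMAX] * kmcmdn / (kmcmdn + cai) ** 2
                      + TRPNMAX * kmtrpn / (kmtrpn + cai) ** 2)
        jtrpn = 0.0
    dy[5] = bcai * (-(ical_i + ipca + icab - 2.0 * inaca_i) * ACAP / (2.0 * F * VMYO)
                    - jup * VNSR / VMYO + jdiff * VSS / VMYO - jtrpn)
    bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                   + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
    dy[6] = bcass * (-(ical_ss - 2.0 * inaca_ss) * ACAP / (2.0 * F * VSS)
                     + jrel * VJSR / VSS - jdiff)
    dy[7] = jup - jtr * VJSR / VNSR
    bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
    dy[8] = bcajsr * (jtr - jrel)

    dy[0] = -(ina + inal + ito + ical_ss + ical_i + icana_ss + icana_i
              + icak_ss + icak_i + ikr + iks + ik1 + inaca_i + inaca_ss
              + inak + ikb + inab + icab + ipca + iclca + iclb + istim)


@njit(cache=True)
def ord_rhs(y, p, s, istim, coupled, mp, dy, yinf, ytau):
    """O'Hara-Rudy (Dutta conductances) + Land coupled derivatives."""
    for k in range(dy.size):
        dy[k] = 0.0
        ytau[k] = 0.0
        yinf[k] = 0.0

    v = y[0]
    nai = y[1]; nass = y[2]
    ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]
    cansr = y[7]; cajsr = y[8]
    nao = p[NAO]; cao = p[CAO]; ko = p[KO]

    ena = RTF * np.log(nao / nai)
    ek = RTF * np.log(ko / ki)
    eks = RTF * np.log((ko + 0.01833 * nao) / (ki + 0.01833 * nai))

    camkt = y[40]
    camka = _camk(cass, camkt)
    fcamk = 1.0 / (1.0 + 0.15 / camka)
    dy[40] = 0.05 * (camka - camkt) * camka - 0.00068 * camkt

    # --- INa (gates 9-14) --------------------------------------------------
    yinf[9] = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    ytau[9] = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                     + 8.552 * np.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    yinf[10] = hss
    ytau[10] = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                      + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    yinf[11] = hss; ytau[11] = ths
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    yinf[12] = hss; ytau[12] = tj
    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    yinf[13] = hssp; ytau[13] = 3.0 * ths
    yinf[14] = hss; ytau[14] = 1.46 * tj
    h = 0.99 * y[10] + 0.01 * y[11]
    hp = 0.99 * y[10] + 0.01 * y[13]
    ina = (p[GNA] * s[S_INA] * (v - ena) * y[9] ** 3
           * ((1.0 - fcamk) * h * y[12] + fcamk * hp * y[14]))

    # --- INaL (15-17) -------------------------------------------------------
    yinf[15] = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    ytau[15] = ytau[9]
    yinf[16] = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488)); ytau[16] = 200.0
    yinf[17] = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488)); ytau[17] = 600.0
    inal = (p[GNAL] * s[S_INAL] * (v - ena) * y[15]
            * ((1.0 - fcamk) * y[16] + fcamk * y[17]))

    # --- Ito (18-23) --------------------------------------------------------
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    yinf[18] = ass; ytau[18] = ta
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    if p[DELTA_EPI] > 0.5:
        delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tif = (4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                          + 0.08004 * np.exp((v + 50.0) / 16.59))) * delta_epi
    tis = (23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                          + 1.780e-8 * np.exp((v + 114.1) / 8.079))) * delta_epi
    yinf[19] = iss; ytau[19] = tif
    yinf[20] = iss; ytau[20] = tis
    yinf[21] = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82)); ytau[21] = ta
    dti_dev = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                + np.exp(-(v - 12.23) / 0.2154))
    dti_rec = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    yinf[22] = iss; ytau[22] = dti_dev * dti_rec * tif
    yinf[23] = iss; ytau[23] = dti_dev * dti_rec * tis
    aif = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    i_g = aif * y[19] + (1.0 - aif) * y[20]
    ip_g = aif * y[22] + (1.0 - aif) * y[23]
    ito = (p[GTO] * s[S_ITO] * (v - ek)
           * ((1.0 - fcamk) * y[18] * i_g + fcamk * y[21] * ip_g))

    # --- ICaL (24-32) -------------------------------------------------------
    yinf[24] = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    ytau[24] = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    yinf[25] = fss; ytau[25] = tff
    yinf[26] = fss; ytau[26] = tfs
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0) + 0.00012 * np.exp(v / 7.0))
    yinf[27] = fss; ytau[27] = tfcaf
    yinf[28] = fss; ytau[28] = tfcas
    yinf[29] = 1.0 / (1.0 + np.exp((v + 18.08) / 2.7916)); ytau[29] = 75.0
    yinf[30] = fss; ytau[30] = 2.5 * tff
    yinf[31] = fss; ytau[31] = 2.5 * tfcaf
    kmn = 0.002; k2n = 1000.0
    km2n = y[29] * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    yinf[32] = anca * k2n / km2n; ytau[32] = 1.0 / km2n

    phical = _phi_ghk(2.0, 1.0, cass, 0.341, cao, v)
    phicana = _phi_ghk(1.0, 0.75, nass, 0.75, nao, v)
    phicak = _phi_ghk(1.0, 0.75, kss, 0.75, ko, v)
    pca = p[PCA] * s[S_ICAL]
    pcap = 1.1 * pca
    afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    f = 0.6 * y[25] + 0.4 * y[26]
    fca = afcaf * y[27] + (1.0 - afcaf) * y[28]
    f_p = 0.6 * y[30] + 0.4 * y[26]
    fcap = afcaf * y[31] + (1.0 - afcaf) * y[28]
    jca = y[29]; nca = y[32]
    op = y[24] * (f * (1.0 - nca) + jca * fca * nca)
    opp = y[24] * (f_p * (1.0 - nca) + jca * fcap * nca)
    ical = (1.0 - fcamk) * pca * phical * op + fcamk * pcap * phical * opp
    icana = ((1.0 - fcamk) * 0.00125 * pca * phicana * op
             + fcamk * 0.00125 * pcap * phicana * opp)
    icak = ((1.0 - fcamk) * 3.574e-4 * pca * phicak * op
            + fcamk * 3.574e-4 * pcap * phicak * opp)

    # --- IKr (33-34) --------------------------------------------------------
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    yinf[33] = xrss
    ytau[33] = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                              + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    yinf[34] = xrss
    ytau[34] = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                              + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    xr = axrf * y[33] + (1.0 - axrf) * y[34]
    rkr = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))
           / (1.0 + np.exp((v - 10.0) / 30.0)))
    ikr = p[GKR] * s[S_IKR] * np.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    # --- IKs (35-36) --------------------------------------------------------
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    yinf[35] = xs1ss
    ytau[35] = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                              + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    yinf[36] = xs1ss
    ytau[36] = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                      + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = p[GKS] * s[S_IKS] * ksca * y[35] * y[36] * (v - eks)

    # --- IK1 (37) -----------------------------------------------------------
    yinf[37] = 1.0 / (1.0 + np.exp(-(v + 2.5538 * ko + 144.59)
                                   / (1.5692 * ko + 3.8115)))
    ytau[37] = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * ko) / 9.493))
    ik1 = p[GK1] * s[S_IK1] * np.sqrt(ko) * rk1 * y[37] * (v - ek)

    # --- pumps, exchangers, background --------------------------------------
    inaca_i = 0.8 * _inaca_kernel(v, nai, cai, nao, cao, p[GNCX] * s[S_INACA])
    inaca_ss = 0.2 * _inaca_kernel(v, nass, cass, nao, cao, p[GNCX] * s[S_INACA])
    inak = _inak_kernel(v, nai, ki, nao, ko, p[PNAK] * s[S_INAK])
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    ikb = p[GKB] * s[S_IKB] * xkb * (v - ek)
    inab = p[PNAB] * s[S_INAB] * _phi_ghk(1.0, 1.0, nai, 1.0, nao, v)
    icab = p[PCAB] * s[S_ICAB] * _phi_ghk(2.0, 1.0, cai, 0.341, cao, v)
    ipca = p[GPCA] * s[S_IPCA] * cai / (0.0005 + cai)

    # --- SR fluxes (38-39) --------------------------------------------------
    bt = 4.75
    jrel_inf = 0.5 * bt * (-ical) / (1.0 + (1.5 / cajsr) ** 8) * p[JREL_INF_SC]
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    yinf[38] = jrel_inf; ytau[38] = tau_rel
    btp = 1.25 * bt
    jrel_infp = 0.5 * btp * (-ical) / (1.0 + (1.5 / cajsr) ** 8) * p[JREL_INF_SC]
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    yinf[39] = jrel_infp; ytau[39] = tau_relp
    jrel = p[JREL_B] * ((1.0 - fcamk) * y[38] + fcamk * y[39])

    jupnp = p[JUP_B] * 0.004375 * cai / (cai + 0.00092)
    jupp = p[JUP_B] * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0039375 * cansr / 15.0
    jup = (1.0 - fcamk) * jupnp + fcamk * jupp - jleak
    jtr = (cansr - cajsr) / 100.0
    jdiff = (cass - cai) / 0.2
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0

    # --- contraction (41-46) ------------------------------------------------
    dxs, dxw, dcatrpn, dtmb, dzs, dzw = _land_derivs(
        y[41], y[42], y[43], y[44], y[45], y[46], cai, mp)
    dy[41] = dxs; dy[42] = dxw; dy[43] = dcatrpn
    dy[44] = dtmb; dy[45] = dzs; dy[46] = dzw

    # --- concentrations and membrane potential ------------------------------
    dy[1] = (-(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab)
             * ACAP / (F * VMYO) + jdiffna * VSS / VMYO)
    dy[2] = -(icana + 3.0 * inaca_ss) * ACAP / (F * VSS) - jdiffna
    dy[3] = (-(ito + ikr + iks + ik1 + ikb + istim - 2.0 * inak)
             * ACAP / (F * VMYO) + jdiffk * VSS / VMYO)
    dy[4] = -icak * ACAP / (F * VSS) - jdiffk

    kmcmdn = 0.00238; kmtrpn = 0.0005
    if coupled == 1:
        bcai = 1.0 / (1.0 + p[CMDNMAX] * kmcmdn / (kmcmdn + cai) ** 2)
        jtrpn = dcatrpn * TRPNMAX
    else:
        bcai = 1.0 / (1.0 + p[CMDNMAX] * kmcmdn / (kmcmdn + cai) ** 2
                      + TRPNMAX * kmtrpn / (kmtrpn + cai) ** 2)
        jtrpn = 0.0
    dy[5] = bcai * (-(ipca + icab - 2.0 * inaca_i) * ACAP / (2.0 * F * VMYO)
                    - jup * VNSR / VMYO + jdiff * VSS / VMYO - jtrpn)
    bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                   + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
    dy[6] = bcass * (-(ical - 2.0 * inaca_ss) * ACAP / (2.0 * F * VSS)
                     + jrel * VJSR / VSS - jdiff)
    dy[7] = jup - jtr * VJSR / VNSR
    bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
    dy[8] = bcajsr * (jtr - jrel)

    dy[0] = -(ina + inal + ito + ical + icana + icak + ikr + iks + ik1
              + inaca_i + inaca_ss + inak + ikb + inab + icab + ipca + istim)


@njit(cache=True)
def rhs_dispatch(variant_id, y, p, s, istim, coupled, mp, dy, yinf, ytau):
    if variant_id == TORORD_ID:
        torord_rhs(y, p, s, istim, coupled, mp, dy, yinf, ytau)
    else:
        ord_rhs(y, p, s, istim, coupled, mp, dy, yinf, ytau)


@njit(cache=True)
def _advance(variant_id, y, t_span, p, s, istim, coupled, mp,
             dy, yinf, ytau, dt_fast, dt_slow):
    """Integrate over t_span (ms) with constant stimulus current."""
    t = 0.0
    n = y.size
    markov = variant_id == TORORD_ID
    while t < t_span - 1e-10:
        rhs_dispatch(variant_id, y, p, s, istim, coupled, mp, dy, yinf, ytau)
        cass = y[6]
        fast = abs(dy[0]) > DV_SWITCH or abs(dy[6]) > DCASS_SWITCH * cass
        dt = dt_fast if fast else dt_slow
        if dt > t_span - t:
            dt = t_span - t
        for k in range(n):
            if ytau[k] > 0.0:
                y[k] = yinf[k] + (y[k] - yinf[k]) * np.exp(-dt / ytau[k])
            else:
                y[k] = y[k] + dt * dy[k]
        if markov:
            # keep the IKr Markov chain on the probability simplex
            tot = y[35] + y[36] + y[37] + y[38] + y[39]
            y[35] /= tot; y[36] /= tot; y[37] /= tot
            y[38] /= tot; y[39] /= tot
        t += dt
    return y


@njit(cache=True)
def pace_kernel(variant_id, y, p, s, mp, coupled,
                cl, n_beats, stim_amp, stim_dur,
                dt_out, rec_from_beat,
                out_v, out_cai, out_ta, out_catrpn,
                dt_fast, dt_slow):
    """Pace ``n_beats`` beats; record beats >= rec_from_beat at dt_out."""
    n = y.size
    dy = np.zeros(n)
    yinf = np.zeros(n)
    ytau = np.zeros(n)
    mech0 = n - 6
    n_per_beat = int(round(cl / dt_out))
    isample = 0
    for beat in range(n_beats):
        rec = beat >= rec_from_beat
        for k_out in range(n_per_beat):
            t0 = k_out * dt_out
            t1 = t0 + dt_out
            if rec:
                out_v[isample] = y[0]
                out_cai[isample] = y[5]
                out_ta[isample] = active_tension_kernel(
                    y[mech0], y[mech0 + 1], y[mech0 + 4], y[mech0 + 5], mp)
                out_catrpn[isample] = y[mech0 + 2]
                isample += 1
            # split the interval at the stimulus-off edge if needed
            if t0 < stim_dur:
                seg_end = stim_dur if stim_dur < t1 else t1
                _advance(variant_id, y, seg_end - t0, p, s, stim_amp,
                         coupled, mp, dy, yinf, ytau, dt_fast, dt_slow)
                if seg_end < t1:
                    _advance(variant_id, y, t1 - seg_end, p, s, 0.0,
                             coupled, mp, dy, yinf, ytau, dt_fast, dt_slow)
            else:
                _advance(variant_id, y, dt_out, p, s, 0.0,
                         coupled, mp, dy, yinf, ytau, dt_fast, dt_slow)
    return isample


@njit(cache=True)
def rest_kernel(variant_id, y, p, s, mp, coupled, duration, dt_fast, dt_slow):
    """Integrate without stimulation for ``duration`` ms."""
    n = y.size
    dy = np.zeros(n)
    yinf = np.zeros(n)
    ytau = np.zeros(n)
    _advance(variant_id, y, duration, p, s, 0.0, coupled, mp,
             dy, yinf, ytau, dt_fast, dt_slow)
    return y
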