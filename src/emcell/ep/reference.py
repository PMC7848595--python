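"""Readable reference transcriptions of the membrane currents and fluxes.

These functions evaluate every transmembrane current (and the SR calcium
fluxes and cytosolic buffer factors) of the two electrophysiology models
from a given state, independently of the compiled simulation kernels.
They exist so the kernels can be audited term by term: the kernel's
dV/dt must equal minus the sum of the currents computed here, and the
calcium bookkeeping of the kernel must balance against the fluxes
computed here.  They are intentionally written in plain, formula-shaped
numpy and are not used on the simulation hot path.
"""

from __future__ import annotations

import numpy as np

from .params import P
from .state import TOR, ORD

R = 8314.0
T = 310.0
F = 96485.0

# cell geometry (cm, uL); shared by both models
L_CELL = 0.01
RAD = 0.0011
VCELL = 1000.0 * 3.14 * RAD * RAD * L_CELL
AGEO = 2.0 * 3.14 * RAD * RAD + 2.0 * 3.14 * RAD * L_CELL
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# CaMKII
KMCAMK = 0.15
ACAMK = 0.05
BCAMK = 0.00068
CAMKO = 0.05
KMCAM = 0.0015

# buffering constants (mM)
KMCMDN = 0.00238
TRPNMAX = 0.07
KMTRPN = 0.0005
BSRMAX = 0.047
KMBSR = 0.00087
BSLMAX = 1.124
KMBSL = 0.0087
CSQNMAX = 10.0
KMCSQN = 0.8


def camk_active(cass, camkt):
    camkb = CAMKO * (1.0 - camkt) / (1.0 + KMCAM / cass)
    return camkb + camkt


def _phi(z, gi, ci, go, co, v):
    """GHK driving-force term z * vF^2/RT * (gi ci e^x - go co)/(e^x - 1), x = z vF/RT.

    Near x = 0 the removable singularity is replaced by its series limit.
    """
    vffrt = v * F * F / (R * T)
    x = z * v * F / (R * T)
    num = gi * ci * np.exp(x) - go * co
    if abs(x) < 1e-7:
        # e^x - 1 ~ x (1 + x/2); z^2 vffrt / x = z F
        return z * F * num / (1.0 + x / 2.0)
    return z * z * vffrt * num / np.expm1(x)


def _activity_coeffs(na, k, ca, cl):
    """Davies-equation single-ion activity coefficients at 37 C."""
    ii = 0.5 * (na + k + cl + 4.0 * ca) / 1000.0
    const_a = 1.82e6 * (74.0 * T) ** (-1.5)
    f = -const_a * (np.sqrt(ii) / (1.0 + np.sqrt(ii)) - 0.3 * ii)
    return np.exp(4.0 * f), np.exp(f)  # (divalent, monovalent)


def _nca_gate(cass, jca, k2n):
    kmn = 0.002
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    return anca, km2n


def _inaca(v, nai, cai, nao, cao, gncx, allo_ca):
    """O'Hara-Rudy sodium-calcium exchanger (shared by both variants)."""
    kna1, kna2, kna3 = 15.0, 5.0, 88.12
    kasymm = 12.5
    wna, wca, wnaca = 6.0e4, 6.0e4, 5.0e3
    kcaon, kcaoff = 1.5e6, 5.0e3
    qna, qca = 0.5224, 0.1670
    vfrt = v * F / (R * T)
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
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
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    kmcaact = 150.0e-6
    allo = 1.0 / (1.0 + (kmcaact / allo_ca) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    return gncx * allo * (jncxna + 2.0 * jncxca)


def _inak(v, nai, ki, nao, ko, pnak):
    """O'Hara-Rudy Na/K ATPase (shared by both variants)."""
    k1p, k1m = 949.5, 182.4
    k2p, k2m = 687.2, 39.4
    k3p, k3m = 1899.0, 79300.0
    k4p, k4m = 639.0, 40.0
    knai0, knao0, delta = 9.073, 27.78, -0.1550
    vfrt = v * F / (R * T)
    knai = knai0 * np.exp(delta * vfrt / 3.0)
    knao = knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
    kki, kko = 0.5, 0.3582
    mgadp, mgatp, kmgatp = 0.05, 9.8, 1.698e-7
    h_conc, ep, khp = 1.0e-7, 4.2, 1.698e-7
    knap, kxkur = 224.0, 292.0
    p_frac = ep / (1.0 + h_conc / khp + nai / knap + ki / kxkur)
    a1 = (k1p * (nai / knai) ** 3) / ((1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0)
    b1 = k1m * mgadp
    a2 = k2p
    b2 = (k2m * (nao / knao) ** 3) / ((1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0)
    a3 = (k3p * (ko / kko) ** 2) / ((1.0 + nao / knao) ** 3 + (1.0 + ko / kko) ** 2 - 1.0)
    b3 = (k3m * p_frac * h_conc) / (1.0 + mgatp / kmgatp)
    a4 = (k4p * mgatp / kmgatp) / (1.0 + mgatp / kmgatp)
    b4 = (k4m * (ki / kki) ** 2) / ((1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    e1 = x1 / (x1 + x2 + x3 + x4)
    e2 = x2 / (x1 + x2 + x3 + x4)
    e3 = x3 / (x1 + x2 + x3 + x4)
    e4 = x4 / (x1 + x2 + x3 + x4)
    jnakna = 3.0 * (e1 * a3 - e2 * b3)
    jnakk = 2.0 * (e4 * b1 - e3 * a1)
    return pnak * (jnakna + jnakk)


def torord_currents(y: np.ndarray, p: np.ndarray, s: np.ndarray) -> dict:
    """All ToR-ORd membrane currents (uA/uF) and SR fluxes (mM/ms)."""
    v = y[TOR.V]
    nai, nass = y[TOR.NAI], y[TOR.NASS]
    ki, kss = y[TOR.KI], y[TOR.KSS]
    cai, cass = y[TOR.CAI], y[TOR.CASS]
    cansr, cajsr = y[TOR.CANSR], y[TOR.CAJSR]
    nao, cao, ko = p[P.NAO], p[P.CAO], p[P.KO]
    clo, cli = p[P.CLO], p[P.CLI]

    ena = (R * T / F) * np.log(nao / nai)
    ek = (R * T / F) * np.log(ko / ki)
    pkna = 0.01833
    eks = (R * T / F) * np.log((ko + pkna * nao) / (ki + pkna * nai))
    ecl = (R * T / F) * np.log(cli / clo)
    camka = camk_active(cass, y[TOR.CAMKT])
    fp = 1.0 / (1.0 + KMCAMK / camka)  # fraction of phosphorylated channels

    ina = (p[P.GNA] * s[0] * (v - ena) * y[TOR.M] ** 3
           * ((1.0 - fp) * y[TOR.H] * y[TOR.J] + fp * y[TOR.HP] * y[TOR.JP]))
    inal = (p[P.GNAL] * s[1] * (v - ena) * y[TOR.ML]
            * ((1.0 - fp) * y[TOR.HL] + fp * y[TOR.HLP]))

    aif = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    ais = 1.0 - aif
    i_gate = aif * y[TOR.IF] + ais * y[TOR.IS]
    ip_gate = aif * y[TOR.IFP] + ais * y[TOR.ISP]
    ito = (p[P.GTO] * s[2] * (v - ek)
           * ((1.0 - fp) * y[TOR.A] * i_gate + fp * y[TOR.AP] * ip_gate))

    # ICaL with ionic-activity (Davies) driving forces, split between the
    # junctional subspace (fraction 0.8) and the bulk myoplasm.
    g2_ss, g1_ss = _activity_coeffs(nass, kss, cass, cli)
    g2_i, g1_i = _activity_coeffs(nai, ki, cai, cli)
    g2_o, g1_o = _activity_coeffs(nao, ko, cao, clo)
    phicals = _phi(2.0, g2_ss, cass, g2_o, cao, v)
    phicanas = _phi(1.0, g1_ss, nass, g1_o, nao, v)
    phicaks = _phi(1.0, g1_ss, kss, g1_o, ko, v)
    phicali = _phi(2.0, g2_i, cai, g2_o, cao, v)
    phicanai = _phi(1.0, g1_i, nai, g1_o, nao, v)
    phicaki = _phi(1.0, g1_i, ki, g1_o, ko, v)
    pca = p[P.PCA] * s[3]
    pcap = 1.1 * pca
    pcana, pcak = 0.00125 * pca, 3.574e-4 * pca
    pcanap, pcakp = 0.00125 * pcap, 3.574e-4 * pcap
    d = y[TOR.D]
    f = 0.6 * y[TOR.FF] + 0.4 * y[TOR.FS]
    fca = _afcaf(v) * y[TOR.FCAF] + (1.0 - _afcaf(v)) * y[TOR.FCAS]
    f_p = 0.6 * y[TOR.FFP] + 0.4 * y[TOR.FS]
    fcap = _afcaf(v) * y[TOR.FCAFP] + (1.0 - _afcaf(v)) * y[TOR.FCAS]
    jca = y[TOR.JCA]
    op_ss = d * (f * (1.0 - y[TOR.NCASS]) + jca * fca * y[TOR.NCASS])
    opp_ss = d * (f_p * (1.0 - y[TOR.NCASS]) + jca * fcap * y[TOR.NCASS])
    op_i = d * (f * (1.0 - y[TOR.NCAI]) + jca * fca * y[TOR.NCAI])
    opp_i = d * (f_p * (1.0 - y[TOR.NCAI]) + jca * fcap * y[TOR.NCAI])
    fss_frac = 0.8
    ical_ss = ((1.0 - fp) * pca * phicals * op_ss + fp * pcap * phicals * opp_ss) * fss_frac
    icana_ss = ((1.0 - fp) * pcana * phicanas * op_ss + fp * pcanap * phicanas * opp_ss) * fss_frac
    icak_ss = ((1.0 - fp) * pcak * phicaks * op_ss + fp * pcakp * phicaks * opp_ss) * fss_frac
    ical_i = ((1.0 - fp) * pca * phicali * op_i + fp * pcap * phicali * opp_i) * (1.0 - fss_frac)
    icana_i = ((1.0 - fp) * pcana * phicanai * op_i + fp * pcanap * phicanai * opp_i) * (1.0 - fss_frac)
    icak_i = ((1.0 - fp) * pcak * phicaki * op_i + fp * pcakp * phicaki * opp_i) * (1.0 - fss_frac)

    ikr = p[P.GKR] * s[4] * np.sqrt(ko / 5.0) * y[TOR.O] * (v - ek)

    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = p[P.GKS] * s[5] * ksca * y[TOR.XS1] * y[TOR.XS2] * (v - eks)

    ak1 = 4.094 / (1.0 + np.exp(0.1217 * (v - ek - 49.934)))
    bk1 = ((15.72 * np.exp(0.0674 * (v - ek - 3.257))
            + np.exp(0.0618 * (v - ek - 594.31)))
           / (1.0 + np.exp(-0.1629 * (v - ek + 14.207))))
    k1ss = ak1 / (ak1 + bk1)
    ik1 = p[P.GK1] * s[6] * np.sqrt(ko / 5.0) * k1ss * (v - ek)

    fss_ncx = 0.35
    inaca_i = (1.0 - fss_ncx) * _inaca(v, nai, cai, nao, cao, p[P.GNCX] * s[7], cai)
    inaca_ss = fss_ncx * _inaca(v, nass, cass, nao, cao, p[P.GNCX] * s[7], cass)

    inak = _inak(v, nai, ki, nao, ko, p[P.PNAK] * s[8])

    xkb = 1.0 / (1.0 + np.exp(-(v - 10.8968) / 23.9871))
    ikb = p[P.GKB] * s[9] * xkb * (v - ek)
    inab = p[P.PNAB] * s[10] * _phi(1.0, 1.0, nai, 1.0, nao, v)
    icab = p[P.PCAB] * s[11] * _phi(2.0, g2_i, cai, g2_o, cao, v)
    ipca = p[P.GPCA] * s[12] * cai / (0.0005 + cai)
    iclca = p[P.GCLCA] * s[13] * (1.0 / (1.0 + 0.1 / cass)) * (v - ecl)
    iclb = p[P.GCLB] * s[14] * (v - ecl)

    # SR fluxes
    btp = 1.25 * 4.75
    jrel_inf_scale = p[P.JREL_INF_SC]
    fjrelp = fp
    jrel = p[P.JREL_B] * ((1.0 - fjrelp) * y[TOR.JRELNP] + fjrelp * y[TOR.JRELP])
    fjupp = fp
    upscale = p[P.JUP_B]
    jupnp = upscale * 0.005425 * cai / (cai + 0.00092)
    jupp = upscale * 2.75 * 0.005425 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0048825 * cansr / 15.0
    jup = (1.0 - fjupp) * jupnp + fjupp * jupp - jleak
    jtr = (cansr - cajsr) / 60.0
    jdiff = (cass - cai) / 0.2
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0

    # buffer factors (the troponin term is handled by the coupling layer)
    cmdnmax = p[P.CMDNMAX]
    bcai_legacy = 1.0 / (1.0 + cmdnmax * KMCMDN / (KMCMDN + cai) ** 2
                         + TRPNMAX * KMTRPN / (KMTRPN + cai) ** 2)
    bcai_coupled = 1.0 / (1.0 + cmdnmax * KMCMDN / (KMCMDN + cai) ** 2)
    bcass = 1.0 / (1.0 + BSRMAX * KMBSR / (KMBSR + cass) ** 2
                   + BSLMAX * KMBSL / (KMBSL + cass) ** 2)
    bcajsr = 1.0 / (1.0 + CSQNMAX * KMCSQN / (KMCSQN + cajsr) ** 2)

    return {
        "INa": ina, "INaL": inal, "Ito": ito,
        "ICaL": ical_ss + ical_i, "ICaNa": icana_ss + icana_i,
        "ICaK": icak_ss + icak_i,
        "ICaL_ss": ical_ss, "ICaL_i": ical_i,
        "ICaNa_ss": icana_ss, "ICaNa_i": icana_i,
        "ICaK_ss": icak_ss, "ICaK_i": icak_i,
        "IKr": ikr, "IKs": iks, "IK1": ik1,
        "INaCa_i": inaca_i, "INaCa_ss": inaca_ss,
        "INaK": inak, "IKb": ikb, "INab": inab, "ICab": icab,
        "IpCa": ipca, "IClCa": iclca, "IClb": iclb,
        "Jrel": jrel, "Jup": jup, "Jtr": jtr, "Jdiff": jdiff,
        "JdiffNa": jdiffna, "JdiffK": jdiffk,
        "Bcai_legacy": bcai_legacy, "Bcai_coupled": bcai_coupled,
        "Bcass": bcass, "Bcajsr": bcajsr,
        "CaMKa": camka,
    }


def _afcaf(v):
    return 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))


def _axrf(v):
    return 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))


def ord_currents(y: np.ndarray, p: np.ndarray, s: np.ndarray) -> dict:
    """All O'Hara-Rudy (Dutta-scaled) membrane currents and SR fluxes."""
    v = y[ORD.V]
    nai, nass = y[ORD.NAI], y[ORD.NASS]
    ki, kss = y[ORD.KI], y[ORD.KSS]
    cai, cass = y[ORD.CAI], y[ORD.CASS]
    cansr, cajsr = y[ORD.CANSR], y[ORD.CAJSR]
    nao, cao, ko = p[P.NAO], p[P.CAO], p[P.KO]

    ena = (R * T / F) * np.log(nao / nai)
    ek = (R * T / F) * np.log(ko / ki)
    pkna = 0.01833
    eks = (R * T / F) * np.log((ko + pkna * nao) / (ki + pkna * nai))
    camka = camk_active(cass, y[ORD.CAMKT])
    fp = 1.0 / (1.0 + KMCAMK / camka)

    ahf, ahs = 0.99, 0.01
    h = ahf * y[ORD.HF] + ahs * y[ORD.HS]
    hp = ahf * y[ORD.HF] + ahs * y[ORD.HSP]
    ina = (p[P.GNA] * s[0] * (v - ena) * y[ORD.M] ** 3
           * ((1.0 - fp) * h * y[ORD.J] + fp * hp * y[ORD.JP]))
    inal = (p[P.GNAL] * s[1] * (v - ena) * y[ORD.ML]
            * ((1.0 - fp) * y[ORD.HL] + fp * y[ORD.HLP]))

    aif = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    i_gate = aif * y[ORD.IF] + (1.0 - aif) * y[ORD.IS]
    ip_gate = aif * y[ORD.IFP] + (1.0 - aif) * y[ORD.ISP]
    ito = (p[P.GTO] * s[2] * (v - ek)
           * ((1.0 - fp) * y[ORD.A] * i_gate + fp * y[ORD.AP] * ip_gate))

    phical = _phi(2.0, 1.0, cass, 0.341, cao, v)
    phicana = _phi(1.0, 0.75, nass, 0.75, nao, v)
    phicak = _phi(1.0, 0.75, kss, 0.75, ko, v)
    pca = p[P.PCA] * s[3]
    pcap = 1.1 * pca
    pcana, pcak = 0.00125 * pca, 3.574e-4 * pca
    pcanap, pcakp = 0.00125 * pcap, 3.574e-4 * pcap
    d = y[ORD.D]
    f = 0.6 * y[ORD.FF] + 0.4 * y[ORD.FS]
    fca = _afcaf(v) * y[ORD.FCAF] + (1.0 - _afcaf(v)) * y[ORD.FCAS]
    f_p = 0.6 * y[ORD.FFP] + 0.4 * y[ORD.FS]
    fcap = _afcaf(v) * y[ORD.FCAFP] + (1.0 - _afcaf(v)) * y[ORD.FCAS]
    nca, jca = y[ORD.NCA], y[ORD.JCA]
    op = d * (f * (1.0 - nca) + jca * fca * nca)
    opp = d * (f_p * (1.0 - nca) + jca * fcap * nca)
    ical = (1.0 - fp) * pca * phical * op + fp * pcap * phical * opp
    icana = (1.0 - fp) * pcana * phicana * op + fp * pcanap * phicana * opp
    icak = (1.0 - fp) * pcak * phicak * op + fp * pcakp * phicak * opp

    xr = _axrf(v) * y[ORD.XRF] + (1.0 - _axrf(v)) * y[ORD.XRS]
    rkr = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))
           * 1.0 / (1.0 + np.exp((v - 10.0) / 30.0)))
    ikr = p[P.GKR] * s[4] * np.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = p[P.GKS] * s[5] * ksca * y[ORD.XS1] * y[ORD.XS2] * (v - eks)

    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * ko) / 9.493))
    ik1 = p[P.GK1] * s[6] * np.sqrt(ko) * rk1 * y[ORD.XK1] * (v - ek)

    inaca_i = 0.8 * _inaca(v, nai, cai, nao, cao, p[P.GNCX] * s[7], cai)
    inaca_ss = 0.2 * _inaca(v, nass, cass, nao, cao, p[P.GNCX] * s[7], cass)
    inak = _inak(v, nai, ki, nao, ko, p[P.PNAK] * s[8])

    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    ikb = p[P.GKB] * s[9] * xkb * (v - ek)
    inab = p[P.PNAB] * s[10] * _phi(1.0, 1.0, nai, 1.0, nao, v)
    icab = p[P.PCAB] * s[11] * _phi(2.0, 1.0, cai, 0.341, cao, v)
    ipca = p[P.GPCA] * s[12] * cai / (0.0005 + cai)

    fjrelp = fp
    jrel = p[P.JREL_B] * ((1.0 - fjrelp) * y[ORD.JRELNP] + fjrelp * y[ORD.JRELP])
    upscale = p[P.JUP_B]
    jupnp = upscale * 0.004375 * cai / (cai + 0.00092)
    jupp = upscale * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0039375 * cansr / 15.0
    jup = (1.0 - fp) * jupnp + fp * jupp - jleak
    jtr = (cansr - cajsr) / 100.0
    jdiff = (cass - cai) / 0.2
    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0

    cmdnmax = p[P.CMDNMAX]
    bcai_legacy = 1.0 / (1.0 + cmdnmax * KMCMDN / (KMCMDN + cai) ** 2
                         + TRPNMAX * KMTRPN / (KMTRPN + cai) ** 2)
    bcai_coupled = 1.0 / (1.0 + cmdnmax * KMCMDN / (KMCMDN + cai) ** 2)
    bcass = 1.0 / (1.0 + BSRMAX * KMBSR / (KMBSR + cass) ** 2
                   + BSLMAX * KMBSL / (KMBSL + cass) ** 2)
    bcajsr = 1.0 / (1.0 + CSQNMAX * KMCSQN / (KMCSQN + cajsr) ** 2)

    return {
        "INa": ina, "INaL": inal, "Ito": ito,
        "ICaL": ical, "ICaNa": icana, "ICaK": icak,
        "ICaL_ss": ical, "ICaL_i": 0.0,
        "ICaNa_ss": icana, "ICaNa_i": 0.0,
        "ICaK_ss": icak, "ICaK_i": 0.0,
        "IKr": ikr, "IKs": iks, "IK1": ik1,
        "INaCa_i": inaca_i, "INaCa_ss": inaca_ss,
        "INaK": inak, "IKb": ikb, "INab": inab, "ICab": icab,
        "IpCa": ipca, "IClCa": 0.0, "IClb": 0.0,
        "Jrel": jrel, "Jup": jup, "Jtr": jtr, "Jdiff": jdiff,
        "JdiffNa": jdiffna, "JdiffK": jdiffk,
        "Bcai_legacy": bcai_legacy, "Bcai_coupled": bcai_coupled,
        "Bcass": bcass, "Bcajsr": bcajsr,
        "CaMKa": camka,
    }


def total_membrane_current(cur: dict) -> float:
    """Sum of all transmembrane currents (uA/uF), excluding the stimulus."""
    return (cur["INa"] + cur["INaL"] + cur["Ito"]
            + cur["ICaL"] + cur["ICaNa"] + cur["ICaK"]
            + cur["IKr"] + cur["IKs"] + cur["IK1"]
            + cur["INaCa_i"] + cur["INaCa_ss"] + cur["INaK"]
            + cur["IKb"] + cur["INab"] + cur["ICab"] + cur["IpCa"]
            + cur["IClCa"] + cur["IClb"])
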