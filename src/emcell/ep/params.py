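"""Parameter sets for the two human ventricular electrophysiology models.

Two model variants are supported:

* ``TORORD`` -- the Tomek-Rodriguez revision of the O'Hara-Rudy model
  (revised ICaL with ionic-activity driving forces, Markov IKr,
  ten Tusscher-style INa, instantaneous rectifying IK1, and
  calcium-sensitive plus background chloride currents).
* ``ORD`` -- the original O'Hara-Rudy model with the Dutta et al.
  conductance rescaling (IKr, IKs, IK1, INaL, ICaL), the variant used
  by regulatory in-silico proarrhythmia work.

The endocardial parameterisation is the base; epicardial and
mid-myocardial cells are derived exclusively through the source models'
published multiplicative scalings (no ad-hoc edits).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Variant", "CellType", "CURRENTS", "EPParams", "make_params", "P"]


class Variant(enum.Enum):
    TORORD = "torord"
    ORD = "ord"


class CellType(enum.Enum):
    ENDO = "endo"
    EPI = "epi"
    MID = "mid"


#: Currents that accept a drug (pore-block) conductance scaling, in the
#: fixed order used by the packed scale vector.
CURRENTS = [
    "INa", "INaL", "Ito", "ICaL", "IKr", "IKs", "IK1",
    "INaCa", "INaK", "IKb", "INab", "ICab", "IpCa", "IClCa", "IClb",
]
CURRENT_INDEX = {name: i for i, name in enumerate(CURRENTS)}


class P:
    """Indices into the packed parameter vector consumed by the kernels."""

    GNA, GNAL, GTO, PCA, GKR, GKS, GK1, GNCX, PNAK, GKB = range(10)
    PNAB, PCAB, GPCA, GCLCA, GCLB = range(10, 15)
    JREL_B, JUP_B, CMDNMAX, DELTA_EPI, JREL_INF_SC = range(15, 20)
    NAO, CAO, KO, CLO, CLI = range(20, 25)
    LEN = 25


# endocardial maximal conductances / permeabilities -----------------------

_TORORD_BASE = {
    "GNa": 11.7802, "GNaL": 0.0279, "Gto": 0.16, "PCa": 8.3757e-5,
    "GKr": 0.0321, "GKs": 0.0011, "GK1": 0.6992, "Gncx": 0.0034,
    "Pnak": 15.4509, "GKb": 0.0189, "PNab": 1.9239e-9, "PCab": 5.9194e-8,
    "GpCa": 5e-4, "GClCa": 0.2843, "GClb": 1.98e-3,
}
_TORORD_EXTRA = {"nao": 140.0, "cao": 1.8, "ko": 5.0, "clo": 150.0, "cli": 24.0}

# Dutta et al. rescaling applied on top of the original O'Hara-Rudy
# endocardial conductances.
_ORD_BASE = {
    "GNa": 75.0, "GNaL": 0.0075 * 2.661, "Gto": 0.02, "PCa": 0.0001 * 1.007,
    "GKr": 0.046 * 1.013, "GKs": 0.0034 * 1.87, "GK1": 0.1908 * 1.698,
    "Gncx": 0.0008, "Pnak": 30.0, "GKb": 0.003, "PNab": 3.75e-10,
    "PCab": 2.5e-8, "GpCa": 0.0005, "GClCa": 0.0, "GClb": 0.0,
}
_ORD_EXTRA = {"nao": 140.0, "cao": 1.8, "ko": 5.4, "clo": 150.0, "cli": 24.0}

# transmural multiplicative scalings (endo -> epi/mid), per source model
_TORORD_EPI = {"GNaL": 0.6, "Gto": 2.0, "PCa": 1.2, "GKr": 1.3, "GKs": 1.4,
               "GK1": 1.2, "Gncx": 1.1, "Pnak": 0.9, "GKb": 0.6}
_TORORD_MID = {"Gto": 2.0, "PCa": 1.8, "GKr": 0.8, "GK1": 1.3, "Gncx": 1.4,
               "Pnak": 0.7}
_ORD_EPI = {"GNaL": 0.6, "Gto": 4.0, "PCa": 1.2, "GKr": 1.3, "GKs": 1.4,
            "GK1": 1.2, "Gncx": 1.1, "Pnak": 0.9, "GKb": 0.6}
_ORD_MID = {"Gto": 4.0, "PCa": 2.5, "GKr": 0.8, "GK1": 1.3, "Gncx": 1.4,
            "Pnak": 0.7}

#: currents that exist in each variant (chloride only in ToR-ORd)
VALID_CURRENTS = {
    Variant.TORORD: set(CURRENTS),
    Variant.ORD: set(CURRENTS) - {"IClCa", "IClb"},
}


@dataclass
class EPParams:
    """Electrophysiology parameter set for one variant / cell type."""

    variant: Variant
    celltype: CellType
    conductances: dict = field(default_factory=dict)
    channel_scale: dict = field(default_factory=dict)
    extracellular: dict = field(default_factory=dict)
    jup_b: float = 1.0        # SERCA scale (epi 1.3)
    jrel_b: float = 1.0       # RyR release scale
    jrel_inf_sc: float = 1.0  # mid-myocardial release-magnitude scaling
    cmdnmax: float = 0.05     # mM, calmodulin buffer (epi x1.3)
    delta_epi: bool = False   # epicardial Ito inactivation-time modifier

    def __post_init__(self):
        if not self.channel_scale:
            self.channel_scale = {c: 1.0 for c in VALID_CURRENTS[self.variant]}

    def validate(self) -> None:
        for cur, s in self.channel_scale.items():
            if cur not in VALID_CURRENTS[self.variant]:
                raise KeyError(f"{cur} is not a current of {self.variant.value}")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"channel_scale[{cur}]={s} outside [0, 1]")

    # --- packing for the compiled kernels ---------------------------------
    def packed(self) -> np.ndarray:
        g = self.conductances
        e = self.extracellular
        out = np.zeros(P.LEN)
        out[P.GNA] = g["GNa"]; out[P.GNAL] = g["GNaL"]; out[P.GTO] = g["Gto"]
        out[P.PCA] = g["PCa"]; out[P.GKR] = g["GKr"]; out[P.GKS] = g["GKs"]
        out[P.GK1] = g["GK1"]; out[P.GNCX] = g["Gncx"]; out[P.PNAK] = g["Pnak"]
        out[P.GKB] = g["GKb"]; out[P.PNAB] = g["PNab"]; out[P.PCAB] = g["PCab"]
        out[P.GPCA] = g["GpCa"]; out[P.GCLCA] = g["GClCa"]; out[P.GCLB] = g["GClb"]
        out[P.JREL_B] = self.jrel_b; out[P.JUP_B] = self.jup_b
        out[P.CMDNMAX] = self.cmdnmax
        out[P.DELTA_EPI] = 1.0 if self.delta_epi else 0.0
        out[P.JREL_INF_SC] = self.jrel_inf_sc
        out[P.NAO] = e["nao"]; out[P.CAO] = e["cao"]; out[P.KO] = e["ko"]
        out[P.CLO] = e["clo"]; out[P.CLI] = e["cli"]
        return out

    def scale_packed(self) -> np.ndarray:
        out = np.ones(len(CURRENTS))
        for cur, s in self.channel_scale.items():
            out[CURRENT_INDEX[cur]] = s
        return out

    def copy(self) -> "EPParams":
        return EPParams(
            variant=self.variant, celltype=self.celltype,
            conductances=dict(self.conductances),
            channel_scale=dict(self.channel_scale),
            extracellular=dict(self.extracellular),
            jup_b=self.jup_b, jrel_b=self.jrel_b,
            jrel_inf_sc=self.jrel_inf_sc, cmdnmax=self.cmdnmax,
            delta_epi=self.delta_epi,
        )


def make_params(variant: Variant | str, celltype: CellType | str) -> EPParams:
    """Published parameter set for a model variant and transmural cell type."""
    variant = Variant(variant) if not isinstance(variant, Variant) else variant
    celltype = CellType(celltype) if not isinstance(celltype, CellType) else celltype

    if variant is Variant.TORORD:
        base, extra = dict(_TORORD_BASE), dict(_TORORD_EXTRA)
        epi_sc, mid_sc = _TORORD_EPI, _TORORD_MID
        jrel_b = 1.5378
    else:
        base, extra = dict(_ORD_BASE), dict(_ORD_EXTRA)
        epi_sc, mid_sc = _ORD_EPI, _ORD_MID
        jrel_b = 1.0

    p = EPParams(variant=variant, celltype=celltype, conductances=base,
                 extracellular=extra, jrel_b=jrel_b)
    if celltype is CellType.EPI:
        for k, s in epi_sc.items():
            p.conductances[k] *= s
        p.jup_b = 1.3
        p.cmdnmax *= 1.3
        p.delta_epi = True
    elif celltype is CellType.MID:
        for k, s in mid_sc.items():
            p.conductances[k] *= s
        p.jrel_inf_sc = 1.7
    return p
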