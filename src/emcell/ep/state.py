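"""State-vector layout, initial conditions and snapshot I/O.

The state ordering below is fixed and versioned (``STATE_VERSION``) so
that snapshots remain portable; the loader validates both the version
and the vector length against the model variant.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .params import Variant, CellType

STATE_VERSION = 1


class TOR:
    """ToR-ORd state indices (43 states)."""
    (V, NAI, NASS, KI, KSS, CAI, CASS, CANSR, CAJSR,
     M, H, HP, J, JP, ML, HL, HLP,
     A, IF, IS, AP, IFP, ISP,
     D, FF, FS, FCAF, FCAS, JCA, FFP, FCAFP,
     NCASS, NCAI,
     XS1, XS2,
     C0, C1, C2, O, I,
     JRELNP, JRELP, CAMKT) = range(43)
    N = 43


class ORD:
    """O'Hara-Rudy state indices (41 states)."""
    (V, NAI, NASS, KI, KSS, CAI, CASS, CANSR, CAJSR,
     M, HF, HS, J, HSP, JP, ML, HL, HLP,
     A, IF, IS, AP, IFP, ISP,
     D, FF, FS, FCAF, FCAS, JCA, FFP, FCAFP, NCA,
     XRF, XRS, XS1, XS2, XK1,
     JRELNP, JRELP, CAMKT) = range(41)
    N = 41


_TOR_NAMES = [
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "h", "hp", "j", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp",
    "nca_ss", "nca_i",
    "xs1", "xs2",
    "ikr_c0", "ikr_c1", "ikr_c2", "ikr_o", "ikr_i",
    "jrel_np", "jrel_p", "camk_trap",
]
_ORD_NAMES = [
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp", "nca",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "jrel_np", "jrel_p", "camk_trap",
]

MECH_NAMES = ["xs", "xw", "catrpn", "tmb", "zetas", "zetaw"]

# slices of the state vector holding gating variables (bounded in [0,1])
GATE_SLICES = {
    Variant.TORORD: slice(TOR.M, TOR.I + 1),
    Variant.ORD: slice(ORD.M, ORD.JRELNP),
}
CONC_INDICES = list(range(1, 9))  # ionic concentrations, strictly positive


def n_states(variant: Variant) -> int:
    return TOR.N if variant is Variant.TORORD else ORD.N


def state_names(variant: Variant) -> list[str]:
    return list(_TOR_NAMES if variant is Variant.TORORD else _ORD_NAMES)


def bootstrap_state(variant: Variant) -> np.ndarray:
    """Approximate resting state used to seed equilibration runs.

    Concentrations are set near their published resting values, gating
    variables to their resting steady states, and the remainder to
    quiescent values.  Shipped snapshots (see ``initial_state``) are
    produced by long equilibration/pacing runs started from here.
    """
    if variant is Variant.TORORD:
        y = np.zeros(TOR.N)
        v = -88.76
        y[TOR.V] = v
        y[TOR.NAI] = 12.1; y[TOR.NASS] = 12.1
        y[TOR.KI] = 142.3; y[TOR.KSS] = 142.3
        y[TOR.CAI] = 8.2e-5; y[TOR.CASS] = 7.0e-5
        y[TOR.CANSR] = 1.52; y[TOR.CAJSR] = 1.52
        y[TOR.M] = 1.0 / (1.0 + np.exp(-(v + 56.86) / 9.03)) ** 2
        hss = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
        y[TOR.H] = hss; y[TOR.J] = hss
        y[TOR.HP] = 1.0 / (1.0 + np.exp((v + 77.55) / 7.43)) ** 2
        y[TOR.JP] = hss
        y[TOR.ML] = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
        y[TOR.HL] = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
        y[TOR.HLP] = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
        ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
        iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
        y[TOR.A] = ass; y[TOR.IF] = iss; y[TOR.IS] = iss
        y[TOR.AP] = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
        y[TOR.IFP] = iss; y[TOR.ISP] = iss
        y[TOR.D] = 0.0
        fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
        y[TOR.FF] = fss; y[TOR.FS] = fss
        y[TOR.FCAF] = 1.0; y[TOR.FCAS] = 1.0
        y[TOR.JCA] = 1.0 / (1.0 + np.exp((v + 18.08) / 2.7916))
        y[TOR.FFP] = fss; y[TOR.FCAFP] = 1.0
        y[TOR.NCASS] = 0.0; y[TOR.NCAI] = 0.0
        y[TOR.XS1] = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
        y[TOR.XS2] = y[TOR.XS1]
        y[TOR.C0] = 0.998; y[TOR.C1] = 1e-3; y[TOR.C2] = 1e-3
        y[TOR.O] = 0.0; y[TOR.I] = 0.0
        y[TOR.JRELNP] = 0.0; y[TOR.JRELP] = 0.0
        y[TOR.CAMKT] = 0.01
        return y
    else:
        y = np.zeros(ORD.N)
        v = -87.8
        y[ORD.V] = v
        y[ORD.NAI] = 7.27; y[ORD.NASS] = 7.27
        y[ORD.KI] = 144.9; y[ORD.KSS] = 144.9
        y[ORD.CAI] = 8.6e-5; y[ORD.CASS] = 8.5e-5
        y[ORD.CANSR] = 1.61; y[ORD.CAJSR] = 1.57
        y[ORD.M] = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
        hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
        y[ORD.HF] = hss; y[ORD.HS] = hss; y[ORD.J] = hss
        y[ORD.HSP] = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
        y[ORD.JP] = hss
        y[ORD.ML] = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
        y[ORD.HL] = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
        y[ORD.HLP] = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
        ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
        iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
        y[ORD.A] = ass; y[ORD.IF] = iss; y[ORD.IS] = iss
        y[ORD.AP] = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
        y[ORD.IFP] = iss; y[ORD.ISP] = iss
        y[ORD.D] = 0.0
        fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
        y[ORD.FF] = fss; y[ORD.FS] = fss
        y[ORD.FCAF] = 1.0; y[ORD.FCAS] = 1.0
        y[ORD.JCA] = 1.0 / (1.0 + np.exp((v + 18.08) / 2.7916))
        y[ORD.FFP] = fss; y[ORD.FCAFP] = 1.0
        y[ORD.NCA] = 0.0
        y[ORD.XRF] = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
        y[ORD.XRS] = y[ORD.XRF]
        y[ORD.XS1] = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
        y[ORD.XS2] = y[ORD.XS1]
        y[ORD.XK1] = 1.0 / (1.0 + np.exp(-(v + 2.5538 * 5.4 + 144.59) / (1.5692 * 5.4 + 3.8115)))
        y[ORD.JRELNP] = 0.0; y[ORD.JRELP] = 0.0
        y[ORD.CAMKT] = 0.01
        return y


# --------------------------------------------------------------------------
# snapshots

SNAPSHOT_DIR = Path(__file__).resolve().parent.parent / "data" / "snapshots"


def snapshot_key(variant, celltype, cl: float, coupled: bool) -> str:
    tag = "em" if coupled else "ep"
    return f"{Variant(variant).value}_{CellType(celltype).value}_cl{int(round(cl))}_{tag}"


def save_snapshot(path, y: np.ndarray, meta: dict) -> None:
    payload = {
        "state_version": STATE_VERSION,
        "meta": meta,
        "state": [float(x) for x in np.asarray(y)],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_snapshot(path) -> tuple[np.ndarray, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("state_version") != STATE_VERSION:
        raise ValueError(f"snapshot {path}: unsupported state version")
    y = np.asarray(payload["state"], dtype=float)
    meta = payload["meta"]
    variant = Variant(meta["variant"])
    n_expected = n_states(variant) + len(MECH_NAMES)
    if y.size != n_expected:
        raise ValueError(
            f"snapshot {path}: state length {y.size} != {n_expected} for {variant.value}")
    return y, meta


def initial_state(variant: Variant | str, celltype: CellType | str,
                  cl: float = 1000.0, coupled: bool = True) -> np.ndarray:
    """Steady-state coupled initial condition from the shipped snapshots.

    Falls back to :func:`bootstrap_state` (with a quiescent mechanics
    state appended) when no snapshot has been generated for the
    requested configuration.
    """
    variant = Variant(variant)
    celltype = CellType(celltype)
    path = SNAPSHOT_DIR / (snapshot_key(variant, celltype, cl, coupled) + ".json")
    if path.exists():
        y, _ = load_snapshot(path)
        return y
    from ..land import initial_mech_state
    ep = bootstrap_state(variant)
    mech = initial_mech_state(ep[5])
    return np.concatenate([ep, mech])
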