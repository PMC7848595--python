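"""Pore-block drug model and the in-silico drug-trial protocol.

Drug action is the simple pore block: at concentration ``c`` a channel
with potency (IC50, h) keeps a conductance fraction
``1 - c^h / (c^h + IC50^h)``.  The trial protocol follows the
reference-compound study design: reach drug-free steady state, apply
the drug, pace 200 further beats, and inspect the final beats for
repolarisation abnormalities, aftercontractions and contractility
escapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ep.params import EPParams, Variant, CellType, VALID_CURRENTS, make_params
from .land import MechParams
from .engine.coupling import pace, default_protocol, BeatTrace
from .biomarkers import BiomarkerReport, full_report, ta_biomarkers, detect_eads
from .snapshots import get_steady_state, DATA_DIR

__all__ = [
    "DrugProfile", "DoseResponse", "block_fraction", "apply_drug",
    "drug_trial", "dose_response_tension", "ead_onset_concentration",
    "load_drug_table", "get_drug",
]

DRUG_TABLE_PATH = DATA_DIR / "drug_table.csv"


def block_fraction(c: float, ic50: float, hill: float) -> float:
    """Fraction of channels blocked at free concentration ``c`` (uM)."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be > 0")
    if c == 0.0:
        return 0.0
    ch = c ** hill
    return ch / (ch + ic50 ** hill)


@dataclass
class DrugProfile:
    """Multichannel potency profile: per-current (IC50 uM, Hill)."""

    name: str
    entries: list = field(default_factory=list)  # (current, ic50_uM, hill)
    eftpc: float | None = None  # uM, maximal effective free therapeutic conc.

    def validate(self, variant: Variant) -> None:
        valid = VALID_CURRENTS[Variant(variant)]
        for cur, ic50, hill in self.entries:
            if cur not in valid:
                raise KeyError(f"{self.name}: current {cur!r} not in {variant}")
            if ic50 <= 0 or hill <= 0:
                raise ValueError(f"{self.name}: invalid potency for {cur}")

    def scale_factors(self, c: float) -> dict:
        return {cur: 1.0 - block_fraction(c, ic50, hill)
                for cur, ic50, hill in self.entries}


PLACEBO = DrugProfile(name="placebo", entries=[])


def load_drug_table(path=DRUG_TABLE_PATH):
    import pandas as pd
    return pd.read_csv(path, comment="#")


def get_drug(name: str, path=DRUG_TABLE_PATH) -> DrugProfile:
    """Look a compound up in the shipped potency table."""
    if name == "placebo":
        return PLACEBO
    df = load_drug_table(path)
    rows = df[df["compound"].str.lower() == name.lower()]
    if rows.empty:
        raise KeyError(f"compound {name!r} not in drug table")
    eftpc = None
    if "eftpc_uM" in rows and rows["eftpc_uM"].notna().any():
        eftpc = float(rows["eftpc_uM"].dropna().iloc[0])
    entries = [(r.current, float(r.ic50_uM), float(r.hill))
               for r in rows.itertuples()]
    return DrugProfile(name=name.lower(), entries=entries, eftpc=eftpc)


def apply_drug(p: EPParams, d: DrugProfile, c: float) -> EPParams:
    """Return a copy of ``p`` with conductances pore-blocked at ``c`` uM.

    Applying a drug to already-drugged parameters is refused: block
    fractions compose multiplicatively, which is never what the trial
    protocol means.
    """
    if getattr(p, "_drug_applied", None):
        raise RuntimeError(
            f"parameters already carry drug {p._drug_applied!r}; "
            "apply drugs to pristine parameters only")
    d.validate(p.variant)
    out = p.copy()
    for cur, fac in d.scale_factors(c).items():
        out.channel_scale[cur] = out.channel_scale.get(cur, 1.0) * fac
    out.validate()
    if d.entries and c > 0:
        out._drug_applied = d.name
    return out


@dataclass
class TrialResult:
    trace: BeatTrace
    report: BiomarkerReport
    control_report: BiomarkerReport
    deltas: dict
    outcome: str  # "ok" | "repolarisation_failure" | "escape"


def drug_trial(variant: Variant | str, celltype: CellType | str,
               d: DrugProfile, c: float, cl: float = 1000.0,
               n_drug_beats: int = 200, coupled: bool = True,
               record_last: int = 10,
               mech_p: MechParams | None = None) -> TrialResult:
    """Run the 200-beat drug protocol from the drug-free steady state.

    Biomarker deltas are control-subtracted at the same cycle length.
    Repolarisation failure is reported as a categorical outcome, not an
    exception.
    """
    variant = Variant(variant)
    celltype = CellType(celltype)
    y0, mech = get_steady_state(variant, celltype, cl, coupled, mech_p=mech_p)
    ep_control = make_params(variant, celltype)
    ep_drug = apply_drug(ep_control, d, c)

    proto_ctrl = default_protocol(variant, cl=cl, n_beats=max(record_last, 2),
                                  record_last=record_last)
    ctrl_trace, _ = pace(y0.copy(), ep_control, mech, proto_ctrl, coupled=coupled)
    ctrl_dev = _developed_tension(ctrl_trace)
    control_report = full_report(ctrl_trace, ctrl_trace.n_beats - 1,
                                 control_developed_tension=ctrl_dev)

    proto = default_protocol(variant, cl=cl, n_beats=n_drug_beats,
                             record_last=record_last)
    trace, _ = pace(y0.copy(), ep_drug, mech, proto, coupled=coupled)
    report = full_report(trace, trace.n_beats - 1,
                         control_developed_tension=ctrl_dev)

    deltas = {}
    for grp in ("ap", "cat", "ta"):
        dsrc, csrc = getattr(report, grp), getattr(control_report, grp)
        for k, val in dsrc.items():
            cv = csrc.get(k)
            if isinstance(val, (int, float)) and isinstance(cv, (int, float)):
                deltas[f"{grp}_{k}"] = val - cv
    outcome = "ok"
    if report.ap.get("repolarisation_failure"):
        outcome = "repolarisation_failure"
    elif report.flags.get("escape_beats"):
        outcome = "escape"
    return TrialResult(trace, report, control_report, deltas, outcome)


def _developed_tension(trace: BeatTrace) -> float:
    ta = ta_biomarkers(trace, trace.n_beats - 1)
    return ta["peak"] - ta["diastolic"]


@dataclass
class DoseResponse:
    concentrations: np.ndarray
    reduction: np.ndarray      # % peak developed-tension reduction vs control
    ic50: float                # uM, fitted
    hill: float                # fitted
    residuals: np.ndarray
    monotone: bool


def fit_hill(concs: np.ndarray, reduction: np.ndarray,
             emax: float = 100.0) -> tuple[float, float, np.ndarray]:
    """Least-squares Hill fit on log-concentration with fixed maximal effect.

    Returns (ic50, hill, residuals).
    """
    from scipy.optimize import curve_fit

    concs = np.asarray(concs, dtype=float)
    reduction = np.asarray(reduction, dtype=float)

    def model(logc, log_ic50, hill):
        return emax / (1.0 + 10.0 ** ((log_ic50 - logc) * hill))

    logc = np.log10(concs)
    # initial guess: concentration nearest half effect, unit slope
    i0 = int(np.argmin(np.abs(reduction - emax / 2.0)))
    popt, _ = curve_fit(model, logc, reduction, p0=[logc[i0], 1.0],
                        maxfev=20000)
    resid = reduction - model(logc, *popt)
    return 10.0 ** popt[0], popt[1], resid


def dose_response_tension(variant: Variant | str, d: DrugProfile,
                          concs, cl: float = 1000.0,
                          celltype: CellType | str = CellType.ENDO,
                          n_drug_beats: int = 200,
                          coupled: bool = True) -> DoseResponse:
    """Peak-tension dose-response curve with a Hill-curve summary.

    The percentage reduction of peak developed tension relative to
    control is computed per concentration and summarised by a Hill fit
    whose maximal effect is fixed at 100% (full block of the driving
    calcium current abolishes contraction in the limit).
    """
    concs = np.asarray(sorted(concs), dtype=float)
    if concs.size < 4:
        raise ValueError("need at least 4 concentrations spanning the transition")
    red = np.empty(concs.size)
    for i, c in enumerate(concs):
        res = drug_trial(variant, celltype, d, c, cl=cl,
                         n_drug_beats=n_drug_beats, coupled=coupled)
        dev_drug = (res.report.ta["peak"] - res.report.ta["diastolic"])
        dev_ctrl = (res.control_report.ta["peak"] - res.control_report.ta["diastolic"])
        red[i] = 100.0 * (1.0 - dev_drug / dev_ctrl)
    ic50, hill, resid = fit_hill(concs, red)
    monotone = bool(np.all(np.diff(red) >= -1.0))
    return DoseResponse(concs, red, ic50, hill, resid, monotone)


def ead_onset_concentration(variant: Variant | str, d: DrugProfile,
                            conc_grid, cl: float = 1000.0,
                            celltype: CellType | str = CellType.ENDO,
                            coupled: bool = True,
                            n_drug_beats: int = 200) -> float | None:
    """Lowest grid concentration whose final trial beats show EADs."""
    for c in sorted(conc_grid):
        res = drug_trial(variant, celltype, d, c, cl=cl, coupled=coupled,
                         n_drug_beats=n_drug_beats)
        flagged = res.report.flags["ead"]
        if not flagged:
            # scan every recorded final beat, not only the last
            for b in range(res.trace.n_beats):
                if detect_eads(res.trace, b)[0]:
                    flagged = True
                    break
        if flagged:
            return float(c)
    return None
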