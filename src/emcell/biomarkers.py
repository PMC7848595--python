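"""Action-potential, calcium-transient and tension biomarkers.

Conventions (fixed across all compared conditions):

* times-to-peak (``tp``) are measured from the stimulus onset of the
  beat;
* the resting potential / diastolic level is the value immediately
  before the stimulus (first sample of the beat), not a global minimum,
  so beats distorted by afterdepolarisations still have a defined
  reference;
* ``APDx`` is measured from the action-potential onset (time of maximal
  upstroke velocity) to the linearly interpolated downward crossing of
  ``peak - x% * (peak - resting)``;
* ``rtX`` of the calcium transient / tension is the time from the peak
  to the interpolated decay by X% of (peak - diastolic);
* the calcium-transient duration used for the electro-mechanical window
  is ``tp + rt90`` (stimulus-to-90%-decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiomarkerReport", "ap_biomarkers", "cat_biomarkers", "ta_biomarkers",
    "detect_eads", "detect_aftercontractions", "detect_escapes",
    "emw", "full_report",
]

UPSTROKE_MIN_DVDT = 10.0   # mV/ms, minimum to call an AP upstroke
EAD_SLOPE_TOL = 0.01       # mV/ms
EAD_PERSIST = 2.0          # ms
EAD_PLATEAU_SKIP = 150.0   # ms after the AP peak before the EAD window opens
AC_SLOPE_FRAC = 2e-4       # of peak tension per ms
AC_PERSIST = 10.0          # ms
AC_SKIP = 10.0             # ms after the tension peak
ESCAPE_FRACTION = 0.1      # of control developed tension


def _beat_arrays(trace, beat: int):
    sub = trace.beat(beat) if trace.n_beats > 1 else trace
    return sub.t, sub


def _cross_down(t, y, thr, start_idx):
    """First downward crossing of thr after start_idx, linearly interpolated."""
    for i in range(start_idx, len(y) - 1):
        if y[i] >= thr > y[i + 1]:
            frac = (y[i] - thr) / (y[i] - y[i + 1])
            return t[i] + frac * (t[i + 1] - t[i])
    return None


def ap_biomarkers(trace, beat: int = 0) -> dict:
    """AP biomarkers of one recorded beat.

    Returns dict with ``tp, apd50, apd90, peak, resting`` plus
    ``escape`` (no upstroke) and ``repolarisation_failure`` flags;
    unresolved quantities are ``None``.
    """
    t, sub = _beat_arrays(trace, beat)
    v = sub.v
    dt = float(np.mean(np.diff(t)))
    resting = float(v[0])
    dvdt = np.diff(v) / np.diff(t)
    out = {"resting": resting, "peak": None, "tp": None,
           "apd50": None, "apd90": None,
           "escape": False, "repolarisation_failure": False}
    if dvdt.max() < UPSTROKE_MIN_DVDT:
        out["escape"] = True
        return out
    i_on = int(np.argmax(dvdt))        # steepest sampling interval
    t_on = t[i_on + 1]                 # end of that interval = AP onset
    i_peak = i_on + int(np.argmax(v[i_on:]))
    out["peak"] = float(v[i_peak])
    out["tp"] = float(t[i_peak] - t[0])
    amp = out["peak"] - resting
    for frac, key in ((0.5, "apd50"), (0.9, "apd90")):
        thr = out["peak"] - frac * amp
        tc = _cross_down(t, v, thr, i_peak)
        if tc is None:
            out["repolarisation_failure"] = True
        else:
            out[key] = float(tc - t_on)
    return out


def _transient_biomarkers(t, y, decay_fracs) -> dict:
    diastolic = float(y[0])
    i_peak = int(np.argmax(y))
    peak = float(y[i_peak])
    out = {"diastolic": diastolic, "peak": peak,
           "tp": float(t[i_peak] - t[0]), "escape": False}
    amp = peak - diastolic
    if amp <= 0:
        out["escape"] = True
        for frac in decay_fracs:
            out[f"rt{int(frac * 100)}"] = None
        return out
    for frac in decay_fracs:
        thr = peak - frac * amp
        tc = _cross_down(t, y, thr, i_peak)
        out[f"rt{int(frac * 100)}"] = (None if tc is None
                                       else float(tc - t[i_peak]))
    return out


def cat_biomarkers(trace, beat: int = 0) -> dict:
    """Calcium-transient biomarkers: tp, rt50, rt90, peak, diastolic, duration90."""
    t, sub = _beat_arrays(trace, beat)
    out = _transient_biomarkers(t, sub.cai, (0.5, 0.9))
    out["duration90"] = (None if out["rt90"] is None
                         else out["tp"] + out["rt90"])
    return out


def ta_biomarkers(trace, beat: int = 0, noise_floor: float = 0.05) -> dict:
    """Active-tension biomarkers: tp, rt50, rt95, peak, diastolic.

    A beat whose developed tension (peak - diastolic) stays below
    ``noise_floor`` (kPa) is annotated as an escape.
    """
    t, sub = _beat_arrays(trace, beat)
    out = _transient_biomarkers(t, sub.ta, (0.5, 0.95))
    if out["peak"] - out["diastolic"] < noise_floor:
        out["escape"] = True
    return out


def _positive_slope_episodes(t, y, window, slope_tol, persist):
    """Times where dy/dt > slope_tol for >= persist ms inside window mask."""
    dydt = np.diff(y) / np.diff(t)
    pos = (dydt > slope_tol) & window[:-1]
    times = []
    run_start = None
    for i, flag in enumerate(pos):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if t[i] - t[run_start] >= persist:
                times.append(float(t[run_start]))
            run_start = None
    if run_start is not None and t[len(pos)] - t[run_start] >= persist:
        times.append(float(t[run_start]))
    return times


def detect_eads(trace, beat: int = 0, slope_tol: float = EAD_SLOPE_TOL,
                plateau_skip: float = EAD_PLATEAU_SKIP) -> tuple[bool, list]:
    """Early afterdepolarisations: positive repolarisation-phase slope.

    The detection window opens ``plateau_skip`` ms after the AP peak (so
    the physiological notch-and-dome rise of epicardial APs is not
    flagged) and closes at the next stimulus; the membrane must sit
    above resting + 10 mV.  The positive slope must exceed ``slope_tol``
    for at least 2 ms.
    """
    t, sub = _beat_arrays(trace, beat)
    v = sub.v
    ap = ap_biomarkers(trace, beat)
    if ap["escape"]:
        return False, []
    i_peak = int(np.argmax(v))
    window = (t >= t[i_peak] + plateau_skip) & (v > ap["resting"] + 10.0)
    times = _positive_slope_episodes(t, v, window, slope_tol, EAD_PERSIST)
    return bool(times), times


def detect_aftercontractions(trace, beat: int = 0,
                             slope_tol: float | None = None) -> tuple[bool, list]:
    """Aftercontractions: secondary tension rise during relaxation.

    ``slope_tol`` defaults to 0.02% of the beat's peak tension per ms,
    sustained for at least 10 ms: aftercontractions at slow pacing rise
    slowly, and the deterministic traces are monotone during normal
    relaxation, so a long persistence window rejects numerical wiggle
    better than a steep slope threshold would.
    """
    t, sub = _beat_arrays(trace, beat)
    ta = sub.ta
    i_peak = int(np.argmax(ta))
    peak = ta[i_peak]
    if peak <= 0:
        return False, []
    if slope_tol is None:
        slope_tol = AC_SLOPE_FRAC * peak
    window = t >= t[i_peak] + AC_SKIP
    times = _positive_slope_episodes(t, ta, window, slope_tol, AC_PERSIST)
    return bool(times), times


def detect_escapes(trace, control_developed_tension: float,
                   threshold: float = ESCAPE_FRACTION) -> list[int]:
    """Beats whose developed tension is below ``threshold`` x control."""
    out = []
    for b in range(trace.n_beats):
        ta = ta_biomarkers(trace, b)
        if ta["peak"] - ta["diastolic"] < threshold * control_developed_tension:
            out.append(b)
    return out


def emw(report: "BiomarkerReport | dict") -> float | None:
    """Electro-mechanical window: APD90 - CaT duration at 90% decay (ms)."""
    if isinstance(report, BiomarkerReport):
        apd90 = report.ap.get("apd90")
        catd90 = report.cat.get("duration90")
    else:
        apd90 = report["ap"].get("apd90")
        catd90 = report["cat"].get("duration90")
    if apd90 is None or catd90 is None:
        return None
    return apd90 - catd90


@dataclass
class BiomarkerReport:
    ap: dict = field(default_factory=dict)
    cat: dict = field(default_factory=dict)
    ta: dict = field(default_factory=dict)
    emw: float | None = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"schema": 1, "ap": self.ap, "cat": self.cat, "ta": self.ta,
                "emw": self.emw, "flags": self.flags}


def full_report(trace, beat: int = 0,
                control_developed_tension: float | None = None) -> BiomarkerReport:
    """Complete biomarker report for one beat of a trace."""
    rep = BiomarkerReport(
        ap=ap_biomarkers(trace, beat),
        cat=cat_biomarkers(trace, beat),
        ta=ta_biomarkers(trace, beat),
    )
    ead, ead_times = detect_eads(trace, beat)
    ac, ac_times = detect_aftercontractions(trace, beat)
    esc = []
    if control_developed_tension is not None:
        esc = detect_escapes(trace, control_developed_tension)
    rep.flags = {"ead": ead, "ead_times": ead_times,
                 "aftercontraction": ac, "aftercontraction_times": ac_times,
                 "escape_beats": esc}
    rep.emw = emw(rep)
    return rep
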