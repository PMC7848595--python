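"""Closed-form synthetic waveforms with exact ground-truth biomarkers.

Used to validate the biomarker extractors and abnormality detectors
against analytically known answers, independent of any ODE model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine.coupling import BeatTrace

__all__ = ["SyntheticWaveformSpec", "generate_waveform"]


@dataclass
class SyntheticWaveformSpec:
    """Specification of a synthetic beat train.

    ``kind='triangle_ap'``: baseline, instant (or linear) rise at
    ``onset`` to baseline+amplitude, linear fall over ``fall`` ms.
    ``kind='raised_cosine_transient'``: raised-cosine pulse of period
    ``rise + fall`` starting at ``onset``.

    ``anomaly``: optional dict with ``type`` in {'ead_hump',
    'aftercontraction_bump', 'dropped_beat'}, plus ``time`` (ms within
    the beat), ``amplitude`` and ``width`` (ms) for the bump types and
    ``beat`` for dropped_beat.
    """

    kind: str = "triangle_ap"
    amplitude: float = 120.0
    baseline: float = -85.0
    onset: float = 5.0
    rise: float = 0.0
    fall: float = 300.0
    cl: float = 1000.0
    n_beats: int = 1
    dt: float = 0.5
    anomaly: dict | None = None

    def __post_init__(self):
        if self.kind not in ("triangle_ap", "raised_cosine_transient"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.anomaly is not None:
            typ = self.anomaly.get("type")
            if typ not in ("ead_hump", "aftercontraction_bump", "dropped_beat"):
                raise ValueError(f"unknown anomaly type {typ!r}")
            if typ != "dropped_beat":
                t_a = self.anomaly["time"]
                if not (self.onset < t_a < self.cl):
                    raise ValueError("anomaly time outside the beat window")


def _triangle(t_in_beat, spec):
    y = np.full_like(t_in_beat, spec.baseline)
    peak_t = spec.onset + spec.rise
    end_t = peak_t + spec.fall
    if spec.rise > 0:
        m = (t_in_beat >= spec.onset) & (t_in_beat < peak_t)
        y[m] = spec.baseline + spec.amplitude * (t_in_beat[m] - spec.onset) / spec.rise
    m = (t_in_beat >= peak_t) & (t_in_beat < end_t)
    y[m] = spec.baseline + spec.amplitude * (1.0 - (t_in_beat[m] - peak_t) / spec.fall)
    return y


def _raised_cosine(t_in_beat, spec):
    period = spec.rise + spec.fall
    y = np.full_like(t_in_beat, spec.baseline)
    m = (t_in_beat >= spec.onset) & (t_in_beat < spec.onset + period)
    s = (t_in_beat[m] - spec.onset) / period
    y[m] = spec.baseline + spec.amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * s))
    return y


def _bump(t_in_beat, time, amplitude, width):
    out = np.zeros_like(t_in_beat)
    m = np.abs(t_in_beat - time) < width / 2.0
    out[m] = amplitude * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t_in_beat[m] - time) / width))
    return out


def generate_waveform(spec: SyntheticWaveformSpec) -> tuple[BeatTrace, dict]:
    """Deterministic closed-form trace plus its exact biomarkers.

    Ground truth (per unperturbed beat): for ``triangle_ap`` --
    ``apd50``/``apd90`` (measured from the upstroke) and ``tp``;
    for ``raised_cosine_transient`` -- ``tp`` and ``rt50/rt90/rt95``
    from the closed-form inverse of the raised cosine.
    """
    n_per = int(round(spec.cl / spec.dt))
    t = np.arange(spec.n_beats * n_per) * spec.dt
    t_in_beat = t % spec.cl
    shape = _triangle if spec.kind == "triangle_ap" else _raised_cosine
    y = shape(t_in_beat, spec)

    truth: dict = {}
    if spec.kind == "triangle_ap":
        for frac, key in ((0.5, "apd50"), (0.9, "apd90")):
            truth[key] = spec.rise + spec.fall * frac
        truth["tp"] = spec.onset + spec.rise
        truth["peak"] = spec.baseline + spec.amplitude
        truth["resting"] = spec.baseline
    else:
        period = spec.rise + spec.fall
        truth["tp"] = spec.onset + period / 2.0
        truth["peak"] = spec.baseline + spec.amplitude
        truth["diastolic"] = spec.baseline
        for frac in (0.5, 0.9, 0.95):
            # after the peak: s* = 1 - arccos(2 f - 1) / (2 pi), f = frac
            s_star = 1.0 - np.arccos(2.0 * frac - 1.0) / (2.0 * np.pi)
            truth[f"rt{int(frac * 100)}"] = (s_star - 0.5) * period

    anomaly = spec.anomaly or {}
    dropped = anomaly.get("type") == "dropped_beat"
    if dropped:
        b = anomaly.get("beat", spec.n_beats - 1)
        y[(t >= b * spec.cl) & (t < (b + 1) * spec.cl)] = spec.baseline
        truth["dropped_beat"] = b

    bump = np.zeros_like(y)
    if anomaly.get("type") in ("ead_hump", "aftercontraction_bump"):
        bump = _bump(t_in_beat, anomaly["time"], anomaly["amplitude"],
                     anomaly.get("width", 40.0))
        truth["anomaly_time"] = anomaly["time"]

    rest_v, rest_ca, rest_ta = -85.0, 1e-4, 0.0
    if spec.kind == "triangle_ap":
        v = y + (bump if anomaly.get("type") == "ead_hump" else 0.0)
        cai = np.full_like(y, rest_ca)
        ta = np.full_like(y, rest_ta)
        if anomaly.get("type") == "aftercontraction_bump":
            ta = ta + bump
    else:
        v = np.full_like(y, rest_v)
        cai = (y - spec.baseline) * 1e-5 + rest_ca  # mM-scaled copy of the pulse
        ta = y - spec.baseline
        if anomaly.get("type") == "aftercontraction_bump":
            ta = ta + bump
        if anomaly.get("type") == "ead_hump":
            v = v + bump

    trace = BeatTrace(
        t=t, v=v, cai=cai, ta=ta, catrpn=np.zeros_like(y),
        stim_times=np.arange(spec.n_beats) * spec.cl,
        cl=spec.cl, dt_out=spec.dt,
        meta={"synthetic": spec.kind},
    )
    return trace, truth
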