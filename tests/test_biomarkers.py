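"""Biomarker extractors and abnormality detectors on closed-form waveforms."""

import numpy as np
import pytest

from emcell.biomarkers import (ap_biomarkers, cat_biomarkers, ta_biomarkers,
                               detect_eads, detect_aftercontractions,
                               detect_escapes, emw, full_report)
from emcell.waveforms import SyntheticWaveformSpec, generate_waveform


def triangle(**kw):
    spec = SyntheticWaveformSpec(kind="triangle_ap", **kw)
    return generate_waveform(spec)


def transient(**kw):
    kw.setdefault("amplitude", 20.0)
    kw.setdefault("baseline", 0.0)
    kw.setdefault("onset", 20.0)
    kw.setdefault("rise", 100.0)
    kw.setdefault("fall", 300.0)
    spec = SyntheticWaveformSpec(kind="raised_cosine_transient", **kw)
    return generate_waveform(spec)


class TestAPBiomarkers:
    def test_triangle_ap_closed_form(self):
        """Rest -85 mV, instant rise to +35 at 5 ms, linear fall to rest at
        305 ms: APD90 = 270 ms, APD50 = 150 ms."""
        trace, truth = triangle()
        ap = ap_biomarkers(trace, 0)
        assert ap["apd90"] == pytest.approx(270.0, abs=1e-9)
        assert ap["apd50"] == pytest.approx(150.0, abs=1e-9)
        assert ap["peak"] == pytest.approx(35.0)
        assert ap["resting"] == pytest.approx(-85.0)
        assert ap["tp"] == pytest.approx(truth["tp"])

    @pytest.mark.parametrize("fall,frac,expect", [
        (200.0, 0.9, 180.0), (200.0, 0.5, 100.0), (400.0, 0.9, 360.0),
    ])
    def test_triangle_family(self, fall, frac, expect):
        trace, _ = triangle(fall=fall)
        key = "apd90" if frac == 0.9 else "apd50"
        assert ap_biomarkers(trace, 0)[key] == pytest.approx(expect, abs=1e-9)

    def test_no_upstroke_annotated_as_escape(self):
        trace, _ = triangle(amplitude=1.0)
        ap = ap_biomarkers(trace, 0)
        assert ap["escape"] and ap["apd90"] is None

    def test_unresolved_repolarisation_flagged(self):
        trace, _ = triangle(fall=2000.0, cl=1000.0)  # never recrosses
        ap = ap_biomarkers(trace, 0)
        assert ap["repolarisation_failure"]
        assert ap["apd90"] is None

    def test_invariant_apd50_le_apd90(self):
        for fall in (150.0, 300.0, 600.0):
            trace, _ = triangle(fall=fall, cl=1000.0)
            ap = ap_biomarkers(trace, 0)
            assert ap["apd50"] <= ap["apd90"]


class TestTransientBiomarkers:
    def test_raised_cosine_closed_form(self):
        trace, truth = transient()
        cat = cat_biomarkers(trace, 0)
        ta = ta_biomarkers(trace, 0)
        # sampled extractor vs analytic inverse of the raised cosine
        assert cat["tp"] == pytest.approx(truth["tp"], abs=0.5)
        assert cat["rt50"] == pytest.approx(truth["rt50"], abs=0.5)
        assert cat["rt90"] == pytest.approx(truth["rt90"], abs=0.5)
        assert ta["rt95"] == pytest.approx(truth["rt95"], abs=0.5)
        assert cat["duration90"] == pytest.approx(truth["tp"] + truth["rt90"],
                                                  abs=1.0)

    def test_rt_ordering(self):
        trace, _ = transient()
        cat = cat_biomarkers(trace, 0)
        ta = ta_biomarkers(trace, 0)
        assert cat["rt50"] <= cat["rt90"]
        assert ta["rt50"] <= ta["rt95"]

    def test_resolution_halving_stability(self):
        vals = {}
        for dt in (0.5, 0.25):
            trace, _ = transient(dt=dt)
            vals[dt] = cat_biomarkers(trace, 0)
        assert abs(vals[0.5]["rt90"] - vals[0.25]["rt90"]) < 0.5
        assert abs(vals[0.5]["tp"] - vals[0.25]["tp"]) < 0.5


class TestDetectors:
    def test_monotone_repolarisation_is_clean(self):
        trace, _ = triangle()
        assert detect_eads(trace, 0) == (False, [])

    def test_injected_ead_hump_detected_inside_hump(self):
        """A 20 mV hump at 80% repolarisation must be flagged, with the
        detection time inside the hump."""
        t_hump = 5.0 + 0.8 * 300.0  # 80% down the fall
        trace, truth = triangle(anomaly={"type": "ead_hump", "time": t_hump,
                                         "amplitude": 20.0, "width": 40.0})
        flagged, times = detect_eads(trace, 0)
        assert flagged
        assert any(abs(tt - t_hump) < 40.0 for tt in times)

    def test_monotone_relaxation_is_clean(self):
        trace, _ = transient()
        assert detect_aftercontractions(trace, 0) == (False, [])

    def test_injected_aftercontraction_detected(self):
        trace, _ = transient(anomaly={"type": "aftercontraction_bump",
                                      "time": 300.0, "amplitude": 5.0,
                                      "width": 60.0})
        flagged, times = detect_aftercontractions(trace, 0)
        assert flagged
        assert any(abs(tt - 300.0) < 60.0 for tt in times)

    def test_dropped_beat_detected_as_escape(self):
        trace, truth = transient(n_beats=3,
                                 anomaly={"type": "dropped_beat", "beat": 1})
        control_dev = 20.0
        assert detect_escapes(trace, control_dev) == [1]

    def test_clean_train_has_no_escapes(self):
        trace, _ = transient(n_beats=3)
        assert detect_escapes(trace, 20.0) == []

    def test_detector_specificity_on_drug_free_models(self):
        """No false EAD/aftercontraction flags on drug-free steady-state
        beats of both variants, all cell types, 0.5-2 Hz."""
        from emcell import make_params, pace
        from emcell.engine.coupling import default_protocol
        from emcell.ep.params import Variant
        from emcell.snapshots import get_steady_state
        configs = [("torord", ct, 1000.0) for ct in ("endo", "epi", "mid")]
        configs += [("ord", ct, 1000.0) for ct in ("endo", "epi", "mid")]
        configs += [("torord", "endo", 500.0), ("torord", "endo", 2000.0),
                    ("torord", "endo", 4000.0)]
        for variant, ct, cl in configs:
            y0, mech = get_steady_state(variant, ct, cl, True)
            proto = default_protocol(Variant(variant), cl=cl, n_beats=2,
                                     record_last=2)
            trace, _ = pace(y0, make_params(variant, ct), mech, proto)
            for b in range(trace.n_beats):
                assert not detect_eads(trace, b)[0], (variant, ct, cl, b)
                assert not detect_aftercontractions(trace, b)[0], (variant, ct, cl, b)


class TestEMW:
    def test_equal_durations_give_zero(self):
        rep = {"ap": {"apd90": 300.0}, "cat": {"duration90": 300.0}}
        assert emw(rep) == 0.0

    def test_absent_inputs_give_none(self):
        rep = {"ap": {"apd90": None}, "cat": {"duration90": 300.0}}
        assert emw(rep) is None

    def test_em_coupled_baseline_emw_shorter_than_ep_only(self):
        """Dynamic troponin buffering shortens the electro-mechanical
        window at baseline.

        Signed EMw (APD90 - CaTD90) is negative at rest because the
        calcium transient outlasts the action potential; the window's
        size is its magnitude, which the faster coupled calcium decay
        reduces."""
        from emcell import make_params, pace
        from emcell.engine.coupling import default_protocol
        from emcell.ep.params import Variant
        from emcell.snapshots import get_steady_state
        vals = {}
        for coupled in (True, False):
            y0, mech = get_steady_state("torord", "endo", 1000.0, coupled)
            proto = default_protocol(Variant.TORORD, n_beats=2, record_last=1)
            trace, _ = pace(y0, make_params("torord", "endo"), mech, proto,
                            coupled=coupled)
            vals[coupled] = full_report(trace, 0).emw
        assert abs(vals[True]) < abs(vals[False])
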