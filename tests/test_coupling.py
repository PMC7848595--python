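"""Coupled-system, integrator and pacing-protocol tests."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from emcell import (Variant, CellType, make_params, MechParams, pace,
                    coupled_rhs, calcium_audit, run_to_steady_state)
from emcell.engine.coupling import PacingProtocol, default_protocol, BeatTrace
from emcell.biomarkers import ap_biomarkers, cat_biomarkers, ta_biomarkers
from emcell.ep.state import GATE_SLICES
from emcell.snapshots import get_steady_state


class TestCalciumBookkeeping:
    @pytest.mark.parametrize("variant", [Variant.TORORD, Variant.ORD])
    @pytest.mark.parametrize("coupled", [True, False])
    def test_conservation_along_a_beat(self, variant, coupled):
        """Volume-weighted total-calcium derivative balances the sarcolemmal
        flux at every sampled state of a paced beat, to 1e-8."""
        y0, mech = get_steady_state(variant, "endo", 1000.0, coupled)
        ep_p = make_params(variant, CellType.ENDO)
        proto = default_protocol(variant, n_beats=1, record_last=1)
        # walk the beat by short pacing segments, auditing the RHS
        y = y0.copy()
        residual = calcium_audit(y, ep_p, mech, coupled=coupled)
        assert residual < 1e-8
        trace, y = pace(y, ep_p, mech, proto, coupled=coupled)
        for frac_state in (y,):
            assert calcium_audit(frac_state, ep_p, mech, coupled=coupled) < 1e-8

    def test_audit_along_transient_states(self, torord_endo_ss, torord_params):
        y0, mech = torord_endo_ss
        proto = default_protocol(Variant.TORORD, n_beats=1, record_last=1)
        y = y0.copy()
        # sample mid-AP states by pacing partial protocols
        for cl_part in (50.0, 120.0, 300.0):
            proto_p = PacingProtocol(cl=cl_part, n_beats=1,
                                     stim_amplitude=-53.0, stim_duration=1.0,
                                     record_last=1)
            _, y_mid = pace(y0.copy(), torord_params, mech, proto_p)
            assert calcium_audit(y_mid, torord_params, mech) < 1e-8


class TestPacing:
    def test_zero_amplitude_stimulus_elicits_no_ap(self, torord_endo_ss,
                                                   torord_params):
        y0, mech = torord_endo_ss
        proto = PacingProtocol(cl=1000.0, n_beats=1, stim_amplitude=-1e-12,
                               stim_duration=1.0, record_last=1)
        trace, _ = pace(y0, torord_params, mech, proto)
        assert trace.v.max() < -60.0

    def test_every_beat_is_captured(self, torord_endo_ss, torord_params):
        """The published stimulus (-53 uA/uF, 1 ms) elicits an AP each beat."""
        y0, mech = torord_endo_ss
        proto = default_protocol(Variant.TORORD, n_beats=4, record_last=4)
        trace, _ = pace(y0, torord_params, mech, proto)
        for b in range(4):
            ap = ap_biomarkers(trace, b)
            assert not ap["escape"]
            assert ap["peak"] > 0.0

    def test_determinism_bit_identical(self, torord_endo_ss, torord_params):
        y0, mech = torord_endo_ss
        proto = default_protocol(Variant.TORORD, n_beats=2, record_last=2)
        t1, yf1 = pace(y0.copy(), torord_params, mech, proto)
        t2, yf2 = pace(y0.copy(), torord_params, mech, proto)
        np.testing.assert_array_equal(t1.v, t2.v)
        np.testing.assert_array_equal(t1.cai, t2.cai)
        np.testing.assert_array_equal(yf1, yf2)

    def test_output_resolution_convergence(self, torord_endo_ss,
                                           torord_params):
        """Halving dt_out changes APD90 by < 0.5 ms."""
        y0, mech = torord_endo_ss
        apds = []
        for dt_out in (0.5, 0.25):
            proto = default_protocol(Variant.TORORD, n_beats=1, record_last=1,
                                     dt_out=dt_out)
            trace, _ = pace(y0.copy(), torord_params, mech, proto)
            apds.append(ap_biomarkers(trace, 0)["apd90"])
        assert abs(apds[0] - apds[1]) < 0.5

    def test_step_size_robustness(self, torord_endo_ss, torord_params):
        """Halving both integrator steps changes APD90 < 0.5 ms and peak
        tension < 0.5%."""
        y0, mech = torord_endo_ss
        proto = default_protocol(Variant.TORORD, n_beats=2, record_last=1)
        tr1, _ = pace(y0.copy(), torord_params, mech, proto)
        tr2, _ = pace(y0.copy(), torord_params, mech, proto,
                      dt_fast=0.0025, dt_slow=0.025)
        assert abs(ap_biomarkers(tr1, 0)["apd90"]
                   - ap_biomarkers(tr2, 0)["apd90"]) < 0.5
        p1, p2 = tr1.ta.max(), tr2.ta.max()
        assert abs(p1 - p2) / p2 < 0.005

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            PacingProtocol(cl=100.0, stim_duration=200.0)
        with pytest.raises(ValueError):
            PacingProtocol(n_beats=0)


class TestGateBoundsAndPositivity:
    @pytest.mark.parametrize("variant,cl", [(Variant.TORORD, 1000.0),
                                            (Variant.ORD, 1000.0),
                                            (Variant.TORORD, 500.0),
                                            (Variant.TORORD, 2000.0)])
    def test_gates_bounded_concentrations_positive(self, variant, cl):
        y0, mech = get_steady_state(variant, "endo", cl, True)
        ep_p = make_params(variant, CellType.ENDO)
        proto = default_protocol(variant, cl=cl, n_beats=3, record_last=3)
        trace, y = pace(y0, ep_p, mech, proto)
        g = GATE_SLICES[variant]
        assert np.all(y[g] >= -1e-12) and np.all(y[g] <= 1.0 + 1e-9)
        assert np.all(y[1:9] > 0.0)
        assert np.all(trace.cai > 0.0)


class TestAgainstReferenceSolver:
    def test_fast_integrator_matches_lsoda(self, torord_endo_ss,
                                           torord_params):
        """One beat with the compiled fixed-schedule scheme agrees with a
        stiff adaptive solver run of the same ODEs (APD90 < 0.5 ms,
        peak calcium < 0.5%)."""
        y0, mech = torord_endo_ss
        proto = default_protocol(Variant.TORORD, n_beats=1, record_last=1)
        trace, _ = pace(y0.copy(), torord_params, mech, proto)

        def rhs(t, y):
            istim = -53.0 if t < 1.0 else 0.0
            return coupled_rhs(t, y, torord_params, mech, istim)

        t_eval = np.arange(0.0, 1000.0, 0.5)
        sol = solve_ivp(rhs, (0.0, 1000.0), y0, method="LSODA",
                        rtol=1e-7, atol=1e-9, t_eval=t_eval, max_step=1.0)
        ref_trace = BeatTrace(t=t_eval, v=sol.y[0], cai=sol.y[5],
                              ta=trace.ta, catrpn=sol.y[-4],
                              stim_times=np.array([0.0]), cl=1000.0,
                              dt_out=0.5)
        apd_fast = ap_biomarkers(trace, 0)["apd90"]
        apd_ref = ap_biomarkers(ref_trace, 0)["apd90"]
        assert abs(apd_fast - apd_ref) < 0.5
        assert trace.cai.max() == pytest.approx(sol.y[5].max(), rel=5e-3)


class TestCouplingPhysiology:
    def test_coupling_preserves_ap_but_reshapes_cat(self):
        """Dynamic troponin buffering leaves the AP unchanged (< 1 mV RMS)
        while the calcium transient grows and decays faster."""
        ep_p = make_params(Variant.TORORD, CellType.ENDO)
        out = {}
        for coupled in (True, False):
            y0, mech = get_steady_state("torord", "endo", 1000.0, coupled)
            proto = default_protocol(Variant.TORORD, n_beats=2, record_last=1)
            trace, _ = pace(y0, ep_p, mech, proto, coupled=coupled)
            out[coupled] = trace
        v_rms = np.sqrt(np.mean((out[True].v - out[False].v) ** 2))
        assert v_rms < 1.0
        cat_em = cat_biomarkers(out[True], 0)
        cat_ep = cat_biomarkers(out[False], 0)
        amp_em = cat_em["peak"] - cat_em["diastolic"]
        amp_ep = cat_ep["peak"] - cat_ep["diastolic"]
        assert amp_em > amp_ep
        assert cat_em["rt90"] < cat_ep["rt90"]
        # decay at 90% closer to the experimental median (315.6 ms)
        assert abs(cat_em["rt90"] - 315.6) < abs(cat_ep["rt90"] - 315.6)


class TestSteadyState:
    def test_already_converged_snapshot_returns_quickly(self, torord_endo_ss,
                                                        torord_params):
        y0, mech = torord_endo_ss
        res = run_to_steady_state(y0, torord_params, mech, cl=1000.0,
                                  max_beats=100, chunk=10)
        assert res.converged
        # the drift criterion needs 50 beats of history; an already-steady
        # start must converge as soon as that window fills
        assert res.n_beats <= 60

    def test_post_convergence_drift_is_negligible(self, torord_endo_ss,
                                                  torord_params):
        """APD90 drifts < 0.1 ms over 50 beats beyond the criterion."""
        y0, mech = torord_endo_ss
        proto = default_protocol(Variant.TORORD, n_beats=50, record_last=50)
        trace, _ = pace(y0, torord_params, mech, proto)
        apd_first = ap_biomarkers(trace, 0)["apd90"]
        apd_last = ap_biomarkers(trace, 49)["apd90"]
        assert abs(apd_last - apd_first) < 0.1

    def test_positive_force_frequency(self):
        """Steady developed tension is higher at 2 Hz than at 0.5 Hz."""
        ep_p = make_params(Variant.TORORD, CellType.ENDO)
        dev = {}
        for cl in (500.0, 2000.0):
            y0, mech = get_steady_state("torord", "endo", cl, True)
            proto = default_protocol(Variant.TORORD, cl=cl, n_beats=2,
                                     record_last=1)
            trace, _ = pace(y0, ep_p, mech, proto)
            ta = ta_biomarkers(trace, 0)
            dev[cl] = ta["peak"] - ta["diastolic"]
        assert dev[500.0] > dev[2000.0]

    def test_snapshot_roundtrip_continues_pacing(self, tmp_path,
                                                 torord_endo_ss,
                                                 torord_params):
        """pace -> save -> load -> pace equals pacing straight through."""
        from emcell.ep.state import save_snapshot, load_snapshot
        y0, mech = torord_endo_ss
        proto2 = default_protocol(Variant.TORORD, n_beats=2, record_last=1)
        trace_thru, _ = pace(y0.copy(), torord_params, mech, proto2)

        proto1 = default_protocol(Variant.TORORD, n_beats=1, record_last=1)
        _, y_mid = pace(y0.copy(), torord_params, mech, proto1)
        path = tmp_path / "mid.json"
        save_snapshot(path, y_mid, {"variant": "torord", "celltype": "endo"})
        y_loaded, _ = load_snapshot(path)
        trace_resume, _ = pace(y_loaded, torord_params, mech, proto1)
        np.testing.assert_allclose(trace_resume.v, trace_thru.v, atol=1e-9)
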