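"""Contraction-model unit and property tests.

The derivative is checked against a second, independently written
transcription of the published equations (kept deliberately different
in structure from both implementations in the package).
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from emcell.land import (MechParams, N_STATES, IDX, initial_mech_state,
                         land_rhs, active_tension, steady_state_force_ca,
                         pack_mech_params)
from emcell.engine import kernels as K


def oracle_land_rhs(y, cai_mm, p: MechParams):
    """Independent transcription of the contraction ODEs (oracle)."""
    ca = 1000.0 * cai_mm                           # uM
    xs, xw, catrpn, tmb, zs, zw = y
    lam = min(1.2, p.lambda_)
    ca50 = p.ca50 + p.beta_1 * min(0.2, lam - 1.0)

    k_uw = 0.026 * p.nu
    k_ws = 0.004 * p.mu
    k_wu = k_uw * (1.0 / p.wfrac - 1.0) - k_ws
    k_su = k_ws * (1.0 / p.dr - 1.0) * p.wfrac
    a_dist = 0.25 * p.tot_a / ((1.0 - p.dr) * p.wfrac + p.dr) * (p.dr / 0.25)
    cds = p.phi * k_ws * (1.0 - p.dr) * p.wfrac / p.dr
    cdw = p.phi * k_uw * (1.0 - p.dr) * (1.0 - p.wfrac) / ((1.0 - p.dr) * p.wfrac)

    xss_half = p.dr * 0.5
    xws_half = (1.0 - p.dr) * p.wfrac * 0.5
    ktm_block = p.k_tm * p.perm50 ** p.n_tm * 0.5 / (0.5 - xss_half - xws_half)

    xu = 1.0 - tmb - xs - xw
    ctr = np.clip(catrpn, 1e-12, 1.0)
    d = np.empty(6)
    d[IDX["catrpn"]] = p.k_trpn * ((ca / ca50) ** p.n_trpn * (1.0 - catrpn) - catrpn)
    d[IDX["tmb"]] = (ktm_block * min(100.0, ctr ** (-p.n_tm / 2.0)) * xu
                     - p.k_tm * ctr ** (p.n_tm / 2.0) * tmb)
    gamma_su = p.gamma_s * max(zs * (zs > 0), (-zs - 1.0) * (zs < -1.0))
    gamma_wu = p.gamma_w * abs(zw)
    d[IDX["xs"]] = k_ws * xw - k_su * xs - gamma_su * xs
    d[IDX["xw"]] = k_uw * xu - k_wu * xw - k_ws * xw - gamma_wu * xw
    d[IDX["zetas"]] = a_dist * p.dlambda_dt - cds * zs
    d[IDX["zetaw"]] = a_dist * p.dlambda_dt - cdw * zw
    return d


def oracle_tension(y, p: MechParams):
    lam = min(1.2, p.lambda_)
    lfac = max(0.0, 1.0 + p.beta_0 * (lam + min(0.87, lam) - 1.87))
    return lfac * p.t_ref / p.dr * ((y[IDX["zetas"]] + 1.0) * y[IDX["xs"]]
                                    + y[IDX["zetaw"]] * y[IDX["xw"]])


def random_mech_states(rng, n):
    states = []
    for _ in range(n):
        fractions = rng.dirichlet(np.ones(4))  # xs, xw, tmb, unbound
        y = np.zeros(N_STATES)
        y[IDX["xs"]], y[IDX["xw"]], y[IDX["tmb"]] = fractions[:3]
        y[IDX["catrpn"]] = rng.uniform(1e-3, 0.99)
        y[IDX["zetas"]] = rng.normal(0, 0.5)
        y[IDX["zetaw"]] = rng.normal(0, 0.5)
        states.append(y)
    return states


class TestDualTranscription:
    def test_rhs_matches_oracle_on_random_states(self, rng):
        p = MechParams()
        for y in random_mech_states(rng, 200):
            cai = 10 ** rng.uniform(-5, -3)
            got = land_rhs(0.0, y, cai, p)
            want = oracle_land_rhs(y, cai, p)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_compiled_kernel_matches_oracle(self, rng):
        p = MechParams()
        mp = pack_mech_params(p)
        for y in random_mech_states(rng, 200):
            cai = 10 ** rng.uniform(-5, -3)
            got = np.array(K._land_derivs(*y, cai, mp))
            want = oracle_land_rhs(y, cai, p)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_tension_matches_oracle(self, rng):
        p = MechParams()
        for y in random_mech_states(rng, 50):
            assert active_tension(y, p) == pytest.approx(oracle_tension(y, p),
                                                         rel=1e-12)

    @pytest.mark.parametrize("lam", [0.85, 0.95, 1.0, 1.1])
    def test_length_dependence_matches_oracle(self, lam, rng):
        p = MechParams(lambda_=lam)
        y = random_mech_states(rng, 1)[0]
        assert active_tension(y, p) == pytest.approx(oracle_tension(y, p),
                                                     rel=1e-12)


class TestTroponinLaw:
    def test_half_occupancy_at_ca50(self):
        """At cai = ca50 and lambda=1 the troponin ODE fixes catrpn = 0.5."""
        p = MechParams()
        ca_mm = p.ca50 / 1000.0
        y = initial_mech_state(ca_mm, p)
        assert y[IDX["catrpn"]] == pytest.approx(0.5, abs=1e-9)
        d = land_rhs(0.0, y, ca_mm, p)
        assert abs(d[IDX["catrpn"]]) < 1e-12

    def test_zero_calcium_decays_to_zero(self):
        """Holding calcium at (numerically) zero relaxes everything to 0."""
        p = MechParams()
        y0 = initial_mech_state(5e-4, p)  # strongly activated start
        sol = solve_ivp(lambda t, y: land_rhs(t, y, 1e-12, p), (0, 20000.0),
                        y0, method="LSODA", rtol=1e-8, atol=1e-12)
        yf = sol.y[:, -1]
        assert yf[IDX["catrpn"]] < 1e-6
        assert yf[IDX["xs"]] < 1e-6 and yf[IDX["xw"]] < 1e-6
        assert active_tension(yf, p) < 1e-4

    def test_cai_must_be_positive(self):
        p = MechParams()
        with pytest.raises(ValueError):
            land_rhs(0.0, initial_mech_state(1e-4, p), -1e-5, p)


class TestInvariants:
    def test_fraction_conservation_under_integration(self):
        """xs + xw + tmb + unbound stays a partition of unity."""
        p = MechParams()
        y0 = initial_mech_state(1e-4, p)

        def rhs(t, y):
            cai = 1e-4 + 4e-4 * np.exp(-((t - 50.0) / 30.0) ** 2)  # a twitch
            return land_rhs(t, y, cai, p)

        sol = solve_ivp(rhs, (0, 600.0), y0, method="LSODA",
                        rtol=1e-9, atol=1e-12, dense_output=False)
        xs, xw, tmb = sol.y[IDX["xs"]], sol.y[IDX["xw"]], sol.y[IDX["tmb"]]
        unbound = 1.0 - xs - xw - tmb
        assert np.all(xs >= -1e-10) and np.all(xw >= -1e-10)
        assert np.all(unbound >= -1e-10)
        # conservation is structural: the four fractions always sum to 1
        np.testing.assert_allclose(xs + xw + tmb + unbound, 1.0, atol=1e-10)

    def test_tension_zero_for_empty_crossbridges(self):
        p = MechParams()
        assert active_tension(np.zeros(N_STATES), p) == 0.0

    def test_tension_linear_in_tref(self, rng):
        y = random_mech_states(rng, 1)[0]
        p1 = MechParams()
        p2 = MechParams(t_ref=2 * p1.t_ref)
        assert active_tension(y, p2) == pytest.approx(2 * active_tension(y, p1))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MechParams(lambda_=1.5)
        with pytest.raises(ValueError):
            MechParams(k_trpn=-0.1)
        with pytest.raises(ValueError):
            MechParams(n_tm=0.5)


class TestForceCalcium:
    def test_two_method_oracle(self):
        """Algebraic steady states agree with long time integration."""
        p = MechParams()
        for ca in (2e-4, 5e-4, 1e-3):
            y_alg = initial_mech_state(ca, p)
            sol = solve_ivp(lambda t, y: land_rhs(t, y, ca, p), (0, 50000.0),
                            initial_mech_state(1e-4, p), method="LSODA",
                            rtol=1e-10, atol=1e-14)
            f_alg = active_tension(y_alg, p)
            f_int = active_tension(sol.y[:, -1], p)
            assert f_int == pytest.approx(f_alg, rel=1e-3)

    def test_curve_is_sigmoid_and_ec50_tracks_ca50(self):
        grid = np.logspace(-4.5, -2.5, 25)
        p1 = MechParams()
        c1 = steady_state_force_ca(p1, grid)
        assert np.all(np.diff(c1["tension"]) >= -1e-9)
        p2 = MechParams(ca50=1.5 * p1.ca50)
        c2 = steady_state_force_ca(p2, grid)
        assert c2["ec50"] > c1["ec50"]
        assert c1["hill"] > 1.0  # cooperative activation

    def test_invalid_grid_rejected(self):
        p = MechParams()
        with pytest.raises(ValueError):
            steady_state_force_ca(p, np.array([1e-3, 1e-4]))

    def test_length_dependence_of_steady_tension(self):
        """Developed steady tension increases with extension ratio on [0.8, 1]."""
        ca = 4e-4
        tensions = []
        for lam in (0.8, 0.9, 1.0):
            p = MechParams(lambda_=lam)
            tensions.append(active_tension(initial_mech_state(ca, p), p))
        assert tensions[0] < tensions[1] < tensions[2]
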