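"""Human active-contraction (crossbridge) model.

Implements the Land human myocyte contraction model: calcium binding to
troponin C, cooperative tropomyosin (thin-filament) activation, and a
three-state crossbridge scheme (unattached U, weakly bound W, strongly
bound S) with distortion variables that carry velocity dependence.

State vector (``MechState``), all dimensionless:

====== =========================================================
index  meaning
====== =========================================================
0      ``xs``     strongly bound (force generating) fraction
1      ``xw``     weakly bound (pre-powerstroke) fraction
2      ``catrpn`` fraction of troponin C with calcium bound
3      ``tmb``    tropomyosin blocked fraction
4      ``zetas``  mean distortion of the S state (signed)
5      ``zetaw``  mean distortion of the W state (signed)
====== =========================================================

The unattached fraction is the derived complement
``u = 1 - tmb - xs - xw``, so ``xs + xw + tmb + u == 1`` identically.

Units: time in ms, rates in 1/ms, calcium in mM (converted internally to
uM, the unit of ``ca50``), tension in kPa (1 kPa = 1 mN/mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MechParams",
    "N_STATES",
    "IDX",
    "initial_mech_state",
    "land_rhs",
    "active_tension",
    "steady_state_force_ca",
    "pack_mech_params",
]

N_STATES = 6
IDX = {"xs": 0, "xw": 1, "catrpn": 2, "tmb": 3, "zetas": 4, "zetaw": 5}


@dataclass
class MechParams:
    """Parameters of the contraction model.

    The defaults are the published human parameter set.  ``n_tm`` (the
    Hill coefficient of cooperative tropomyosin activation) and ``k_tm``
    (the tropomyosin rate constant, the unblocking rate) are the two
    parameters exposed to the calibrator.
    """

    t_ref: float = 120.0       # kPa, tension at full S-state occupancy (xs = dr)
    ca50: float = 0.805        # uM, half-activation calcium of troponin C at lambda = 1
    n_trpn: float = 2.0        # troponin Hill coefficient
    k_trpn: float = 0.1        # 1/ms, troponin unbinding rate
    n_tm: float = 5.0          # Hill coefficient of cooperative activation
    k_tm: float = 0.021        # 1/ms, tropomyosin rate constant (unblocking)
    perm50: float = 0.35       # half-activation of the permissive fraction
    dr: float = 0.25           # duty ratio: steady S fraction at full activation
    wfrac: float = 0.5         # steady W/(U+W) partition at full activation
    tot_a: float = 25.0        # distortion forcing scale
    beta_0: float = 2.3        # length dependence of tension
    beta_1: float = -2.4       # uM per unit lambda, length dependence of ca50
    gamma_s: float = 0.0085    # 1/ms, distortion-dependent S detachment scale
    gamma_w: float = 0.615     # 1/ms, distortion-dependent W detachment scale
    phi: float = 2.23          # distortion decay scale
    nu: float = 7.0            # multiplier on the base U->W rate 0.026/ms
    mu: float = 3.0            # multiplier on the base W->S rate 0.004/ms
    lambda_: float = 1.0       # extension ratio (isometric protocols: constant)
    dlambda_dt: float = 0.0    # 1/ms

    def __post_init__(self) -> None:
        if not (0.8 <= self.lambda_ <= 1.2):
            raise ValueError(f"lambda_={self.lambda_} outside validated range [0.8, 1.2]")
        for name in ("k_trpn", "k_tm", "t_ref", "ca50"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_trpn < 1 or self.n_tm < 1:
            raise ValueError("Hill coefficients must be >= 1")

    # derived rates -----------------------------------------------------
    @property
    def k_uw(self) -> float:
        return 0.026 * self.nu

    @property
    def k_ws(self) -> float:
        return 0.004 * self.mu

    @property
    def k_wu(self) -> float:
        return self.k_uw * (1.0 / self.wfrac - 1.0) - self.k_ws

    @property
    def k_su(self) -> float:
        return self.k_ws * (1.0 / self.dr - 1.0) * self.wfrac

    @property
    def a_dist(self) -> float:
        dr, w = self.dr, self.wfrac
        return (0.25 * self.tot_a) / ((1.0 - dr) * w + dr) * (dr / 0.25)

    @property
    def c_ds(self) -> float:
        return self.phi * self.k_ws * (1.0 - self.dr) * self.wfrac / self.dr

    @property
    def c_dw(self) -> float:
        return self.phi * self.k_uw * (1.0 - self.dr) * (1.0 - self.wfrac) / ((1.0 - self.dr) * self.wfrac)

    @property
    def k_tm_block(self) -> float:
        xsss = self.dr * 0.5
        xwss = (1.0 - self.dr) * self.wfrac * 0.5
        return self.k_tm * (self.perm50 ** self.n_tm) * 0.5 / (0.5 - xsss - xwss)

    def ca50_at_length(self) -> float:
        """Length-corrected half activation (uM)."""
        return self.ca50 + self.beta_1 * min(0.2, self.lambda_ - 1.0)

    def length_factor(self) -> float:
        lam = min(1.2, self.lambda_)
        return max(0.0, 1.0 + self.beta_0 * (lam + min(0.87, lam) - 1.87))

    def with_(self, **kw) -> "MechParams":
        return replace(self, **kw)


def initial_mech_state(cai: float = 1e-4, p: MechParams | None = None) -> np.ndarray:
    """Resting state consistent with a diastolic free calcium ``cai`` (mM)."""
    p = p or MechParams()
    ca = cai * 1000.0
    r = (ca / p.ca50_at_length()) ** p.n_trpn
    catrpn = r / (1.0 + r)
    catrpn = min(max(catrpn, 1e-8), 1.0 - 1e-8)
    # tropomyosin / crossbridge equilibrium at this catrpn
    kb = p.k_tm_block * min(100.0, catrpn ** (-p.n_tm / 2.0))
    ku = p.k_tm * catrpn ** (p.n_tm / 2.0)
    # solve the linear steady state of (xs, xw, tmb)
    # dxs=0: xs = (k_ws/k_su) xw ; dxw=0: xw = k_uw u /(k_wu+k_ws);  dtmb=0: tmb = kb u / ku
    a_xw = p.k_uw / (p.k_wu + p.k_ws)
    a_xs = p.k_ws / p.k_su * a_xw
    a_tm = kb / ku
    u = 1.0 / (1.0 + a_xw + a_xs + a_tm)
    y = np.zeros(N_STATES)
    y[IDX["xs"]] = a_xs * u
    y[IDX["xw"]] = a_xw * u
    y[IDX["catrpn"]] = catrpn
    y[IDX["tmb"]] = a_tm * u
    return y


def land_rhs(t: float, m: np.ndarray, cai: float, p: MechParams) -> np.ndarray:
    """Time derivative of the contraction state.

    Parameters
    ----------
    t : float
        Time (ms); the model is autonomous, kept for ODE-solver signatures.
    m : ndarray, shape (6,)
        Mechanics state (see module docstring for ordering).
    cai : float
        Free intracellular calcium (mM), > 0.
    p : MechParams
    """
    if cai <= 0:
        raise ValueError("cai must be > 0")
    xs, xw, catrpn, tmb, zetas, zetaw = m
    ca = cai * 1000.0  # uM

    catrpn_c = min(max(catrpn, 1e-12), 1.0)
    dcatrpn = p.k_trpn * ((ca / p.ca50_at_length()) ** p.n_trpn * (1.0 - catrpn) - catrpn)

    xu = 1.0 - tmb - xs - xw
    kb = p.k_tm_block * min(100.0, catrpn_c ** (-p.n_tm / 2.0))
    ku = p.k_tm * catrpn_c ** (p.n_tm / 2.0)
    dtmb = kb * xu - ku * tmb

    gamma_rate_s = p.gamma_s * max(zetas if zetas > 0.0 else 0.0,
                                   -zetas - 1.0 if zetas < -1.0 else 0.0)
    gamma_rate_w = p.gamma_w * abs(zetaw)
    dxs = p.k_ws * xw - p.k_su * xs - gamma_rate_s * xs
    dxw = p.k_uw * xu - p.k_wu * xw - p.k_ws * xw - gamma_rate_w * xw

    dzetas = p.a_dist * p.dlambda_dt - p.c_ds * zetas
    dzetaw = p.a_dist * p.dlambda_dt - p.c_dw * zetaw

    out = np.array([dxs, dxw, dcatrpn, dtmb, dzetas, dzetaw])
    if not np.all(np.isfinite(out)):
        bad = [k for k, i in IDX.items() if not np.isfinite(out[i])]
        raise FloatingPointError(f"non-finite contraction derivative in {bad}")
    return out


def active_tension(m: np.ndarray, p: MechParams) -> float:
    """Active tension (kPa) developed by the current crossbridge state."""
    xs, xw = m[IDX["xs"]], m[IDX["xw"]]
    zetas, zetaw = m[IDX["zetas"]], m[IDX["zetaw"]]
    return p.length_factor() * (p.t_ref / p.dr) * ((zetas + 1.0) * xs + zetaw * xw)


def _steady_state_at_ca(ca_mm: float, p: MechParams) -> np.ndarray:
    """Algebraic steady state at constant calcium (root of the RHS)."""
    return initial_mech_state(ca_mm, p)


def steady_state_force_ca(p: MechParams, cai_grid: np.ndarray) -> dict:
    """Steady-state calcium-force relationship.

    For each calcium level in ``cai_grid`` (mM, ascending) the algebraic
    steady state of the model is computed and its tension evaluated; a Hill
    curve is then fitted to the resulting F-Ca relationship.

    Returns a dict with ``cai`` (mM), ``tension`` (kPa), fitted ``ec50``
    (mM), ``hill`` and per-point convergence ``ok`` flags.
    """
    cai_grid = np.asarray(cai_grid, dtype=float)
    if np.any(cai_grid <= 0) or np.any(np.diff(cai_grid) <= 0):
        raise ValueError("cai_grid must be positive and strictly ascending")
    tension = np.empty_like(cai_grid)
    ok = np.ones(cai_grid.shape, dtype=bool)
    for i, ca in enumerate(cai_grid):
        try:
            y = _steady_state_at_ca(ca, p)
            d = land_rhs(0.0, y, ca, p)
            ok[i] = np.max(np.abs(d)) < 1e-9
            tension[i] = active_tension(y, p)
        except (ValueError, FloatingPointError):
            ok[i] = False
            tension[i] = np.nan

    fmax = np.nanmax(tension)
    ec50 = np.nan
    hill = np.nan
    if fmax > 0 and np.sum(ok) >= 4:
        half = 0.5 * fmax
        t_ok, c_ok = tension[ok], cai_grid[ok]
        # bracket the half-maximum crossing and refine by interpolation on
        # the continuous steady-state curve
        above = np.nonzero(t_ok >= half)[0]
        if above.size and above[0] > 0:
            lo, hi = c_ok[above[0] - 1], c_ok[above[0]]
            ec50 = brentq(
                lambda c: active_tension(_steady_state_at_ca(c, p), p) - half, lo, hi
            )
            # local log-log slope of F/(Fmax-F) at EC50 = Hill coefficient
            eps = 1.02
            f1 = active_tension(_steady_state_at_ca(ec50 / eps, p), p)
            f2 = active_tension(_steady_state_at_ca(ec50 * eps, p), p)
            f1 = min(f1, fmax * (1 - 1e-9))
            f2 = min(f2, fmax * (1 - 1e-9))
            y1 = np.log(f1 / (fmax - f1))
            y2 = np.log(f2 / (fmax - f2))
            hill = (y2 - y1) / (2 * np.log(eps))
    return {"cai": cai_grid, "tension": tension, "ok": ok, "ec50": ec50, "hill": hill}


# ---------------------------------------------------------------------------
# packing for the compiled engine

MECH_PACK_LEN = 17


def pack_mech_params(p: MechParams) -> np.ndarray:
    """Flatten parameters (plus derived rates) for the compiled kernels."""
    return np.array([
        p.t_ref, p.ca50_at_length(), p.n_trpn, p.k_trpn,
        p.n_tm, p.k_tm, p.k_tm_block,
        p.k_uw, p.k_ws, p.k_wu, p.k_su,
        p.a_dist, p.c_ds, p.c_dw,
        p.gamma_s, p.gamma_w,
        p.length_factor(),
    ])
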