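"""Bidirectionally coupled electro-mechanical cell simulations.

The electrophysiology model supplies free intracellular calcium to the
contraction model; the contraction model's dynamic troponin-C occupancy
is fed back into the calcium ODE, replacing the electrophysiology
model's steady-state troponin buffer (calmodulin and the other buffers
are untouched).  With ``coupled=False`` the published steady-state
troponin buffer is retained and the contraction model is driven one-way
(the electrophysiology-only comparator used in drug studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ep.params import EPParams, Variant
from ..ep import reference as ref
from ..ep.state import n_states, TOR, ORD
from ..land import MechParams, pack_mech_params, N_STATES as MECH_N
from . import kernels as K

__all__ = [
    "PacingProtocol", "BeatTrace", "SteadyStateResult", "IntegrationError",
    "coupled_rhs", "ep_rhs", "pace", "run_to_steady_state", "calcium_audit",
]


class IntegrationError(RuntimeError):
    pass


@dataclass
class PacingProtocol:
    """Square-pulse pacing protocol.

    The default stimulus follows the source model convention: the
    caller should pass the variant-appropriate amplitude/duration
    (ToR-ORd: -53 uA/uF for 1 ms; ORd: -80 uA/uF for 0.5 ms), available
    via :func:`default_protocol`.
    """

    cl: float = 1000.0            # ms
    n_beats: int = 1
    stim_amplitude: float = -53.0  # uA/uF
    stim_duration: float = 1.0     # ms
    record_last: int = 1
    dt_out: float = 0.5            # ms

    def __post_init__(self):
        if not (self.cl > self.stim_duration > 0):
            raise ValueError("require cl > stim_duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        self.record_last = int(min(self.record_last, self.n_beats))


def default_protocol(variant: Variant, **kw) -> PacingProtocol:
    amp, dur = ((-53.0, 1.0) if Variant(variant) is Variant.TORORD
                else (-80.0, 0.5))
    kw.setdefault("stim_amplitude", amp)
    kw.setdefault("stim_duration", dur)
    return PacingProtocol(**kw)


@dataclass
class BeatTrace:
    """Uniformly sampled trace of one or more recorded beats."""

    t: np.ndarray       # ms, from the start of the first recorded beat
    v: np.ndarray       # mV
    cai: np.ndarray     # mM
    ta: np.ndarray      # kPa
    catrpn: np.ndarray  # troponin-C occupancy (dimensionless)
    stim_times: np.ndarray  # ms, stimulus onsets inside the trace
    cl: float
    dt_out: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.v) == len(self.cai) == len(self.ta) == n):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.stim_times)

    def beat(self, i: int) -> "BeatTrace":
        """Single-beat sub-trace (i counts recorded beats from 0)."""
        per = int(round(self.cl / self.dt_out))
        sl = slice(i * per, (i + 1) * per)
        return BeatTrace(
            t=self.t[sl] - self.t[sl][0], v=self.v[sl], cai=self.cai[sl],
            ta=self.ta[sl], catrpn=self.catrpn[sl],
            stim_times=np.array([0.0]), cl=self.cl, dt_out=self.dt_out,
            meta=self.meta,
        )

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t_ms": self.t, "v_mV": self.v, "cai_mM": self.cai,
            "ta_kPa": self.ta, "catrpn": self.catrpn,
        })

    def to_csv(self, path) -> None:
        import json
        header = "# emcell trace " + json.dumps(
            {"cl": self.cl, "dt_out": self.dt_out,
             "stim_times": list(map(float, self.stim_times)), **self.meta})
        with open(path, "w") as fh:
            fh.write(header + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeatTrace":
        import json
        import pandas as pd
        with open(path) as fh:
            first = fh.readline()
            df = pd.read_csv(fh)
        meta = json.loads(first.split("# emcell trace ", 1)[1])
        stim = np.asarray(meta.pop("stim_times"))
        cl = meta.pop("cl")
        dt_out = meta.pop("dt_out")
        return cls(t=df["t_ms"].to_numpy(), v=df["v_mV"].to_numpy(),
                   cai=df["cai_mM"].to_numpy(), ta=df["ta_kPa"].to_numpy(),
                   catrpn=df["catrpn"].to_numpy(), stim_times=stim,
                   cl=cl, dt_out=dt_out, meta=meta)


def _variant_id(variant: Variant) -> int:
    return K.TORORD_ID if variant is Variant.TORORD else K.ORD_ID


def _check_finite(y: np.ndarray, names, where: str) -> None:
    if not np.all(np.isfinite(y)):
        bad = [names[i] if i < len(names) else f"mech[{i - len(names)}]"
               for i in np.nonzero(~np.isfinite(y))[0]]
        raise IntegrationError(f"non-finite state {bad} {where}")


def coupled_rhs(t: float, y: np.ndarray, ep_p: EPParams, mech_p: MechParams,
                i_stim: float = 0.0, coupled: bool = True) -> np.ndarray:
    """Full coupled time derivative (true ODE form, usable by any solver)."""
    n = y.size
    dy = np.zeros(n)
    yinf = np.zeros(n)
    ytau = np.zeros(n)
    K.rhs_dispatch(_variant_id(ep_p.variant), y, ep_p.packed(),
                   ep_p.scale_packed(), i_stim, 1 if coupled else 0,
                   pack_mech_params(mech_p), dy, yinf, ytau)
    rl = ytau > 0
    dy[rl] = (yinf[rl] - y[rl]) / ytau[rl]
    if not np.all(np.isfinite(dy)):
        from ..ep.state import state_names
        names = state_names(ep_p.variant) + ["xs", "xw", "catrpn", "tmb", "zetas", "zetaw"]
        bad = [names[i] for i in np.nonzero(~np.isfinite(dy))[0]]
        raise IntegrationError(f"non-finite derivative for state(s) {bad}")
    return dy


def ep_rhs(t: float, s: np.ndarray, p: EPParams, i_stim: float = 0.0,
           j_trpn_buffer: float | None = None) -> np.ndarray:
    """Electrophysiology-only derivative.

    ``j_trpn_buffer`` (mM/ms) is the rate of calcium binding to troponin
    C supplied by the contraction model; when given, it replaces the
    published steady-state troponin buffer in the free-calcium ODE.
    When ``None`` the legacy buffer is used (uncoupled model).
    """
    p.validate()
    n_ep = n_states(p.variant)
    if s.size != n_ep:
        raise ValueError(f"expected {n_ep} states for {p.variant.value}")
    y = np.concatenate([s, np.zeros(MECH_N)])
    y[n_ep + 2] = 0.5  # inert mechanics placeholder
    mech_p = MechParams()
    dy = coupled_rhs(t, y, p, mech_p, i_stim, coupled=False)[:n_ep]
    if j_trpn_buffer is not None:
        cur = (ref.torord_currents if p.variant is Variant.TORORD
               else ref.ord_currents)(s, p.packed(), p.scale_packed())
        cai_idx = TOR.CAI if p.variant is Variant.TORORD else ORD.CAI
        flux = dy[cai_idx] / cur["Bcai_legacy"]
        dy[cai_idx] = cur["Bcai_coupled"] * (flux - j_trpn_buffer)
    return dy


def pace(y0: np.ndarray, ep_p: EPParams, mech_p: MechParams,
         proto: PacingProtocol, coupled: bool = True,
         dt_fast: float = K.DT_FAST, dt_slow: float = K.DT_SLOW,
         ) -> tuple[BeatTrace, np.ndarray]:
    """Pace the coupled cell and return (trace of recorded beats, final state).

    The stimulus is a square current pulse at the start of every cycle;
    the integrator lands exactly on pulse edges, so no stimulus is ever
    missed or smeared.
    """
    ep_p.validate()
    n_ep = n_states(ep_p.variant)
    y = np.array(y0, dtype=float)
    if y.size != n_ep + MECH_N:
        raise ValueError(
            f"state length {y.size} != {n_ep + MECH_N} for {ep_p.variant.value}")
    n_per = int(round(proto.cl / proto.dt_out))
    n_rec = proto.record_last * n_per
    out_v = np.empty(n_rec)
    out_cai = np.empty(n_rec)
    out_ta = np.empty(n_rec)
    out_ctr = np.empty(n_rec)
    mp = pack_mech_params(mech_p)
    K.pace_kernel(_variant_id(ep_p.variant), y, ep_p.packed(),
                  ep_p.scale_packed(), mp, 1 if coupled else 0,
                  proto.cl, proto.n_beats, proto.stim_amplitude,
                  proto.stim_duration, proto.dt_out,
                  proto.n_beats - proto.record_last,
                  out_v, out_cai, out_ta, out_ctr, dt_fast, dt_slow)
    from ..ep.state import state_names
    names = state_names(ep_p.variant)
    _check_finite(y, names, "at end of pacing protocol")
    for arr, label in ((out_v, "V"), (out_cai, "Cai"), (out_ta, "Ta")):
        if not np.all(np.isfinite(arr)):
            beat = int(np.nonzero(~np.isfinite(arr))[0][0] // n_per)
            raise IntegrationError(
                f"non-finite {label} in recorded beat {beat}")
    t = np.arange(n_rec) * proto.dt_out
    stim_times = np.arange(proto.record_last) * proto.cl
    trace = BeatTrace(
        t=t, v=out_v, cai=out_cai, ta=out_ta, catrpn=out_ctr,
        stim_times=stim_times, cl=proto.cl, dt_out=proto.dt_out,
        meta={"variant": ep_p.variant.value, "celltype": ep_p.celltype.value,
              "coupled": coupled, "stim_amplitude": proto.stim_amplitude,
              "stim_duration": proto.stim_duration},
    )
    return trace, y


@dataclass
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    n_beats: int
    metrics: dict


def run_to_steady_state(y0: np.ndarray, ep_p: EPParams, mech_p: MechParams,
                        cl: float = 1000.0, tol: float = 5e-4,
                        max_beats: int = 1500, window: int = 10,
                        coupled: bool = True, chunk: int = 50,
                        stim_amplitude: float | None = None,
                        stim_duration: float | None = None,
                        ) -> SteadyStateResult:
    """Pace until APD90, CaT peak and Ta peak are beat-to-beat stable.

    Convergence requires both (a) the relative spread of each metric
    over the last ``window`` beats to fall below ``tol`` (default
    0.05%), and (b) the APD90 drift over the last 50 beats to be below
    0.1 ms — the spread alone can be satisfied during a slow monotone
    drift.  Non-convergence within ``max_beats`` returns
    ``converged=False`` rather than raising.
    """
    from ..biomarkers import ap_biomarkers

    proto0 = default_protocol(ep_p.variant)
    amp = stim_amplitude if stim_amplitude is not None else proto0.stim_amplitude
    dur = stim_duration if stim_duration is not None else proto0.stim_duration
    y = np.array(y0, dtype=float)
    history: dict[str, list[float]] = {"apd90": [], "cat_peak": [], "ta_peak": []}
    total = 0
    spreads: dict[str, float] = {}
    while total < max_beats:
        n = min(chunk, max_beats - total)
        proto = PacingProtocol(cl=cl, n_beats=n, stim_amplitude=amp,
                               stim_duration=dur, record_last=n, dt_out=1.0)
        trace, y = pace(y, ep_p, mech_p, proto, coupled=coupled)
        per = int(round(cl / proto.dt_out))
        for b in range(n):
            beat = trace.beat(b)
            ap = ap_biomarkers(beat, 0)
            history["apd90"].append(ap.get("apd90") or np.nan)
            history["cat_peak"].append(float(beat.cai.max()))
            history["ta_peak"].append(float(beat.ta.max()))
        total += n
        if total >= window:
            spreads = {}
            ok = True
            for k, vals in history.items():
                w = np.asarray(vals[-window:])
                if np.any(~np.isfinite(w)):
                    ok = False
                    spreads[k] = np.inf
                    continue
                ref_v = np.abs(w).max()
                spreads[k] = (w.max() - w.min()) / ref_v if ref_v > 0 else 0.0
                ok = ok and spreads[k] < tol
            apd = history["apd90"]
            if len(apd) >= 50 and np.isfinite(apd[-1]) and np.isfinite(apd[-50]):
                spreads["apd90_drift_50"] = abs(apd[-1] - apd[-50])
                ok = ok and spreads["apd90_drift_50"] < 0.1
            elif len(apd) < 50:
                ok = False
            if ok:
                return SteadyStateResult(y, True, total, spreads)
    return SteadyStateResult(y, False, total, spreads)


# ---------------------------------------------------------------------------
# calcium bookkeeping audit

def calcium_audit(y: np.ndarray, ep_p: EPParams, mech_p: MechParams,
                  i_stim: float = 0.0, coupled: bool = True) -> float:
    """Residual of total-calcium conservation at one state (mM/ms, myoplasm units).

    The time derivative of total cell calcium (free + buffered in every
    compartment, volume-weighted) must equal the net sarcolemmal calcium
    flux.  Returns the absolute residual, which should vanish to solver
    precision for a consistent set of flux equations.
    """
    variant = ep_p.variant
    n_ep = n_states(variant)
    cur = (ref.torord_currents if variant is Variant.TORORD
           else ref.ord_currents)(y[:n_ep], ep_p.packed(), ep_p.scale_packed())
    dy = coupled_rhs(0.0, y, ep_p, mech_p, i_stim, coupled)
    cai_i, cass_i = (TOR.CAI, TOR.CASS) if variant is Variant.TORORD else (ORD.CAI, ORD.CASS)
    cansr_i, cajsr_i = (TOR.CANSR, TOR.CAJSR) if variant is Variant.TORORD else (ORD.CANSR, ORD.CAJSR)

    bcai = cur["Bcai_coupled"] if coupled else cur["Bcai_legacy"]
    dca_myo_total = dy[cai_i] / bcai          # free + cmdn (+ trpn if legacy)
    if coupled:
        dca_myo_total += K.TRPNMAX * dy[n_ep + 2]  # dynamic troponin store
    dca_ss_total = dy[cass_i] / cur["Bcass"]
    dca_jsr_total = dy[cajsr_i] / cur["Bcajsr"]
    dca_nsr = dy[cansr_i]

    internal = (ref.VMYO * dca_myo_total + ref.VSS * dca_ss_total
                + ref.VNSR * dca_nsr + ref.VJSR * dca_jsr_total)
    ica_tot = (cur["ICaL"] + cur["ICab"] + cur["IpCa"]
               - 2.0 * (cur["INaCa_i"] + cur["INaCa_ss"]))
    sarcolemmal = -ica_tot * ref.ACAP / (2.0 * ref.F)
    return abs(internal - sarcolemmal) / ref.VMYO
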