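"""Three-stage experiment emulation.

Stage 1 drives the model to a chemostat steady state (long integration plus
a Newton polish with the two moiety constraints substituted for redundant
balance rows).  Stage 2 runs block-wise feast/famine cycles with explicit
broth-volume dynamics: feed phase (volume rises, no outflow), outflow phase
(constant rate removing exactly the feed-phase volume gain), rest phase
(closed).  Stage 3 — the enrichment run — lives in
:mod:`yeastff.labeling` and reuses the cycle runner here.

Integration restarts at every phase boundary, so no solver step straddles a
flow discontinuity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.optimize import root

from .constants import SECONDS_PER_HOUR, glc_g_per_l_to_mm
from .model import BATCH, BoundaryFlow, GlycogenTables, YeastModel
from .params import ParameterSet

__all__ = [
    "FeedProtocol",
    "SteadyStateError",
    "ProtocolError",
    "Trajectory",
    "run_chemostat",
    "run_cycles",
    "cycle_summary",
]


class SteadyStateError(RuntimeError):
    """No admissible steady state found; message reports the worst residual."""


class ProtocolError(RuntimeError):
    """Protocol configuration or integration failure (e.g. negative volume)."""


@dataclass(frozen=True)
class FeedProtocol:
    """Chemostat + feast/famine cycle definition.

    The feed pump rate during the feed window is chosen so that the total
    glucose supplied per cycle equals the chemostat supply over one cycle
    length (average-supply equivalence):
    ``F = D * V0 * cycle_s / (feed_s * multiplier)``.
    """

    dilution_per_h: float = 0.1
    cs_chem_g_per_l: float = 28.5
    cycle_s: float = 400.0
    feed_s: float = 20.0
    multiplier: float = 20.0
    outflow_end_s: float = 260.0
    n_cycles: int = 20
    residence_times: float = 5.0
    biomass_gdw_per_l: float = 12.0
    vacuole_fraction: float = 0.10
    label_fraction: float = 0.99
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if not (0 < self.feed_s < self.outflow_end_s <= self.cycle_s):
            raise ProtocolError("require 0 < feed window < outflow end <= cycle length")
        if self.multiplier <= 0 or self.dilution_per_h <= 0:
            raise ProtocolError("multiplier and dilution rate must be > 0")

    @property
    def dilution_per_s(self) -> float:
        return self.dilution_per_h / SECONDS_PER_HOUR

    @property
    def cs_chem_mm(self) -> float:
        return glc_g_per_l_to_mm(self.cs_chem_g_per_l)

    @property
    def feed_conc_mm(self) -> float:
        return self.multiplier * self.cs_chem_mm

    def feed_pump_rate(self, volume: float) -> float:
        """Volumetric feed rate (L s^-1) during the feed window."""
        return (self.dilution_per_s * volume * self.cycle_s
                / (self.feed_s * self.multiplier))

    def flow_at(self, cycle_time: float, volume: float,
                label_frac: float = 0.0) -> BoundaryFlow:
        """Boundary flow at a given cycle time (used by the generic RHS)."""
        if cycle_time < self.feed_s:
            return BoundaryFlow("feed", self.feed_pump_rate(volume),
                                self.feed_conc_mm, label_frac)
        if cycle_time < self.outflow_end_s:
            gain = self.feed_pump_rate(volume) * self.feed_s
            return BoundaryFlow("outflow", gain / (self.outflow_end_s - self.feed_s))
        return BATCH

    def with_cycles(self, n: int) -> "FeedProtocol":
        return replace(self, n_cycles=int(n))


# ----------------------------------------------------------------------
# Chemostat steady state
# ----------------------------------------------------------------------

def _chemostat_flow(protocol: FeedProtocol) -> BoundaryFlow:
    return BoundaryFlow("chemostat", protocol.dilution_per_s, protocol.cs_chem_mm)


def run_chemostat(params: ParameterSet, protocol: FeedProtocol,
                  y0: np.ndarray | None = None, sensing: bool = True,
                  glycogen: GlycogenTables | None = None,
                  model: YeastModel | None = None,
                  horizon_s: float = 4.0e5, residual_tol: float = 1e-6,
                  require_physiological: bool = True) -> tuple[np.ndarray, YeastModel]:
    """Find the chemostat steady state.

    Integrates from ``y0`` (default: the shipped calibrated steady state)
    over several residence times, then polishes with a root solve in which
    the redundant AMP and NADH balance rows are replaced by the adenylate
    and nicotinamide conservation constraints.  Returns ``(state, model)``.

    Raises :class:`SteadyStateError` if the residual tolerance cannot be
    met, a concentration is non-positive, or (with
    ``require_physiological``) the state is degenerate (no glucose uptake
    or collapsed ATP charge).
    """
    if model is None:
        model = YeastModel(params, protocol.biomass_gdw_per_l,
                           protocol.vacuole_fraction, sensing=sensing,
                           glycogen=glycogen)
    if y0 is None:
        from .model import load_chemostat_state

        y0 = load_chemostat_state("calibrated")
    y0 = np.asarray(y0, dtype=float)
    flow = _chemostat_flow(protocol)

    a0, n0 = model.moiety_totals(y0)
    i_amp = model.i["AMP"]
    i_nadh = model.i["NADH"]
    vol = y0[-1]

    def residual(yy):
        y_full = np.concatenate([yy, [vol]])
        r = model.rhs(y_full, 0.0, flow, chemostat_mode=True)[: model.i_vol]
        at, nt = model.moiety_totals(y_full)
        r = r.copy()
        r[i_amp] = at - a0
        r[i_nadh] = nt - n0
        return r

    def polish_and_check(y_guess):
        sol = root(residual, y_guess[: model.i_vol], method="hybr", tol=1e-12)
        y_ss = np.concatenate([sol.x, [vol]])
        r_full = model.rhs(y_ss, 0.0, flow, chemostat_mode=True)[: model.i_vol]
        worst = float(np.max(np.abs(r_full)))
        problems = []
        if worst > residual_tol:
            problems.append(f"worst residual {worst:.3e} mM/s")
        if np.any(y_ss[: model.i_vol] <= 1e-9):
            problems.append("non-positive concentrations")
        if require_physiological and not problems:
            uptake = model.fluxes(y_ss, 0.0, chemostat_mode=True)[0]
            atp_frac = y_ss[model.i["ATP"]] / max(model.moiety_totals(y_ss)[0],
                                                  1e-12)
            if uptake <= 0.0 or atp_frac < 0.05:
                problems.append(
                    f"degenerate state (uptake {uptake:.3e} mM/s, "
                    f"ATP charge fraction {atp_frac:.3f})")
        return y_ss, problems

    # fast path: Newton polish straight from the warm start
    y_ss, problems = polish_and_check(y0)
    if not problems:
        return y_ss, model

    # fall back to a long integration before polishing
    def rhs(y, t):
        return model.rhs(y, t, flow, chemostat_mode=True)

    t_int = np.linspace(0.0, horizon_s, 40)
    y_traj = odeint(rhs, y0, t_int, rtol=1e-8, atol=1e-10, mxstep=50000)
    y_ss, problems = polish_and_check(y_traj[-1])
    if problems:
        raise SteadyStateError("no admissible steady state: "
                               + "; ".join(problems))
    return y_ss, model


# ----------------------------------------------------------------------
# Feast/famine cycles
# ----------------------------------------------------------------------

@dataclass
class Trajectory:
    """Dense cycle trajectory on a fixed output grid.

    ``Y`` holds the total-concentration states; ``L`` (optional) the
    labelled concentrations for carbon species.
    """

    times: np.ndarray
    cycle_time: np.ndarray
    cycle_index: np.ndarray
    Y: np.ndarray
    model: YeastModel
    protocol: FeedProtocol
    L: np.ndarray | None = None
    _fluxes: np.ndarray | None = field(default=None, repr=False)

    def species(self, name: str) -> np.ndarray:
        return self.Y[:, self.model.i[name]]

    @property
    def volume(self) -> np.ndarray:
        return self.Y[:, self.model.i_vol]

    def labelled(self, name: str) -> np.ndarray:
        if self.L is None:
            raise ValueError("trajectory carries no labelled states")
        return self.L[:, self.model.net.l_index[name]]

    def enrichment(self, name: str) -> np.ndarray:
        """Labelled fraction in percent; 0 where the total pool is 0."""
        tot = self.species(name)
        lab = self.labelled(name)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(tot > 0, lab / np.where(tot > 0, tot, 1.0), 0.0)
        return 100.0 * e

    def flux_table(self) -> np.ndarray:
        """Net fluxes at every output time (n_t x n_reactions)."""
        if self._fluxes is None:
            out = np.empty((len(self.times), self.model.net.n_reactions))
            for k, (t, y) in enumerate(zip(self.cycle_time, self.Y)):
                out[k] = self.model.fluxes(y, t)
            self._fluxes = out
        return self._fluxes

    def flux(self, reaction: str) -> np.ndarray:
        return self.flux_table()[:, self.model.net.r_index[reaction]]

    def cycle_mask(self, c: int) -> np.ndarray:
        return self.cycle_index == c

    @property
    def n_cycles(self) -> int:
        return int(self.cycle_index.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_s, variable, value, unit, cycle_index)."""
        names = self.model.net.species_names
        rows = []
        for j, name in enumerate(names):
            rows.append(pd.DataFrame({
                "time_s": self.times, "variable": name, "value": self.Y[:, j],
                "unit": "mM", "cycle_index": self.cycle_index}))
        rows.append(pd.DataFrame({
            "time_s": self.times, "variable": "VOL",
            "value": self.Y[:, self.model.i_vol], "unit": "L",
            "cycle_index": self.cycle_index}))
        fx = self.flux_table()
        for j, name in enumerate(self.model.net.reaction_names):
            rows.append(pd.DataFrame({
                "time_s": self.times, "variable": f"v_{name}", "value": fx[:, j],
                "unit": "mM/s", "cycle_index": self.cycle_index}))
        return pd.concat(rows, ignore_index=True)


def _phase_grid(t0: float, t1: float, t_res: float) -> np.ndarray:
    n = max(int(round((t1 - t0) / t_res)), 2)
    return np.linspace(t0, t1, n + 1)


def _integrate(rhs, y0, tgrid, rtol, atol):
    y = odeint(rhs, y0, tgrid, rtol=rtol, atol=atol, mxstep=50000)
    undershoot = y.min()
    if undershoot < -1e-6:
        raise ProtocolError(f"state undershoot {undershoot:.3e} exceeds guard")
    return np.maximum(y, 0.0) if undershoot < 0 else y


def run_cycles(ss_state: np.ndarray, params: ParameterSet | None,
               protocol: FeedProtocol, model: YeastModel | None = None,
               n_cycles: int | None = None, t_res: float = 1.0,
               label_frac: float | None = None,
               L0: np.ndarray | None = None,
               rtol: float | None = None, atol: float | None = None) -> Trajectory:
    """Integrate repeated feast/famine cycles from a chemostat steady state.

    With ``label_frac`` set, the labelled-fraction balances are co-integrated
    (see :mod:`yeastff.labeling`); ``L0`` gives initial labelled
    concentrations (default: all unlabelled).
    """
    if model is None:
        model = YeastModel(params, protocol.biomass_gdw_per_l,
                           protocol.vacuole_fraction)
    rtol = protocol.rtol if rtol is None else rtol
    atol = protocol.atol if atol is None else atol
    n_cycles = protocol.n_cycles if n_cycles is None else n_cycles

    labelled = label_frac is not None
    if labelled:
        from .labeling import make_joint_rhs

        if L0 is None:
            L0 = np.zeros(model.net.n_labelled)
        y = np.concatenate([np.asarray(ss_state, float), np.asarray(L0, float)])
    else:
        y = np.asarray(ss_state, dtype=float).copy()

    t_abs, t_cyc, idx, states = [], [], [], []
    for c in range(n_cycles):
        v0 = y[model.i_vol]
        if v0 <= 0:
            raise ProtocolError("negative or zero broth volume")
        pump = protocol.feed_pump_rate(v0)
        gain = pump * protocol.feed_s
        out_rate = gain / (protocol.outflow_end_s - protocol.feed_s)
        phases = [
            (0.0, protocol.feed_s,
             BoundaryFlow("feed", pump, protocol.feed_conc_mm,
                          label_frac or 0.0)),
            (protocol.feed_s, protocol.outflow_end_s,
             BoundaryFlow("outflow", out_rate)),
            (protocol.outflow_end_s, protocol.cycle_s, BATCH),
        ]
        for (p0, p1, flow) in phases:
            if labelled:
                rhs = make_joint_rhs(model, flow, label_frac)
            else:
                def rhs(yy, tt, _flow=flow):
                    return model.rhs(yy, tt, _flow)
            grid = _phase_grid(p0, p1, t_res)
            seg = _integrate(rhs, y, grid, rtol, atol)
            keep = slice(0, -1) if p1 < protocol.cycle_s else slice(0, None)
            t_abs.append(c * protocol.cycle_s + grid[keep])
            t_cyc.append(grid[keep])
            idx.append(np.full(len(grid[keep]), c, dtype=int))
            states.append(seg[keep])
            y = seg[-1]

    times = np.concatenate(t_abs)
    Yall = np.vstack(states)
    n_tot = model.n_states
    traj = Trajectory(
        times=times, cycle_time=np.concatenate(t_cyc),
        cycle_index=np.concatenate(idx), Y=Yall[:, :n_tot],
        model=model, protocol=protocol,
        L=Yall[:, n_tot:] if labelled else None)
    return traj


# ----------------------------------------------------------------------
# Summaries
# ----------------------------------------------------------------------

def cycle_summary(traj: Trajectory) -> dict:
    """Per-cycle extrema and derived flux metrics.

    Returns a dict with a tidy ``table`` (per cycle/variable extrema with
    time of maximum), per-cycle ``tre_synth_over_hxk_pct`` (100 x max
    trehalose-synthesis flux / max hexose-phosphorylation flux) and a
    cumulative CO2 proxy from decarboxylation plus the pyruvate sink
    stoichiometry (3 CO2 per pyruvate equivalent routed to the TCA sink).
    """
    rows = []
    ratios = {}
    co2 = {}
    fx = traj.flux_table()
    names = traj.model.net.species_names
    rnames = traj.model.net.reaction_names
    j_tps1 = traj.model.net.r_index["TPS1"]
    j_glk = traj.model.net.r_index["GLK"]
    j_pdc = traj.model.net.r_index["PDC"]
    j_spyr = traj.model.net.r_index["SINKPYR"]
    for c in range(traj.n_cycles):
        m = traj.cycle_mask(c)
        tt = traj.cycle_time[m]
        for j, name in enumerate(names):
            series = traj.Y[m, j]
            k = int(np.argmax(series))
            rows.append((c, "species", name, float(series.max()),
                         float(series.min()), float(tt[k])))
        for j, name in enumerate(rnames):
            series = fx[m, j]
            k = int(np.argmax(series))
            rows.append((c, "flux", name, float(series.max()),
                         float(series.min()), float(tt[k])))
        ratios[c] = 100.0 * fx[m, j_tps1].max() / fx[m, j_glk].max()
        co2[c] = float(np.trapezoid(fx[m, j_pdc] + 3.0 * fx[m, j_spyr], tt))
    table = pd.DataFrame(rows, columns=["cycle", "kind", "name", "max", "min",
                                        "t_of_max"])
    return {"table": table, "tre_synth_over_hxk_pct": ratios,
            "co2_proxy_mm": co2}
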