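"""Two-step parameter identification.

Step 1: combinatorial screening — bounded nonlinear least squares for many
(enzyme subset x weighting vector) combinations, every subset containing
the trehalose cycle.  Step 2: L1-regularized re-estimation of the winning
subset over a lambda grid, with the penalty pulling estimates toward a
reference parameter set.

The total objective decomposes exactly as

    cost = data error + lambda * sum |theta_ref - theta|

with theta in log10 space (parameters are fitted as log10 values inside
symmetric bounds, which makes the penalty scale-invariant across Vmax- and
Km-class constants).  The L1 term is expressed through the square-root
residual trick, ``r_j = sqrt(lambda * |delta_j|)``, so a standard
least-squares solver minimizes the exact L1-penalized objective; a
subgradient treatment at delta = 0 is not needed because the solver only
evaluates the objective.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bundles import ObservationBundle
from .model import GlycogenTables
from .params import ESTIMABLE_KEYS, ParameterSet, TREHALOSE_CYCLE_REACTIONS
from .protocol import FeedProtocol, run_chemostat, run_cycles

__all__ = [
    "EstimationConfig",
    "FitResult",
    "CycleSimulator",
    "build_residuals",
    "fit_subset",
    "combinatorial_screen",
    "regularization_sweep",
    "fold_change_report",
]

#: Residual value substituted (per data point) when a trial simulation fails;
#: large but finite so the optimizer can retreat.
PENALTY_RESIDUAL = 1.0e3


@dataclass(frozen=True)
class EstimationConfig:
    """One estimation problem: free parameters, weights, regularization."""

    subset: tuple[str, ...]
    free_names: tuple[str, ...]
    reference: ParameterSet
    lam: float = 0.0
    weights: dict = field(default_factory=dict)  # (table or (table, series)) -> w
    bounds_decades: float = 2.0
    max_nfev: int = 60
    n_starts: int = 1
    start_jitter: float = 0.15
    seed: int = 0
    xtol: float = 1e-8
    ftol: float = 1e-8

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        for name in self.free_names:
            rxn, const = name.split(".", 1)
            if rxn not in self.subset:
                raise ValueError(f"free parameter {name} outside subset")
            if const not in ESTIMABLE_KEYS.get(rxn, ()):
                raise ValueError(f"{name} is not an estimable constant")
        for w in self.weights.values():
            if w <= 0:
                raise ValueError("weights must be > 0")


@dataclass
class FitResult:
    """Outcome of one bounded least-squares fit."""

    estimate: ParameterSet
    data_error: float
    param_error: float          # lambda * sum |delta_log10|
    param_deviation: float      # sum |delta_log10| (unscaled)
    cost: float
    residual: np.ndarray
    success: bool
    message: str
    subset_id: str
    weights: dict
    nfev: int = 0

    @property
    def total_cost(self) -> float:
        return self.data_error + self.param_error


class CycleSimulator:
    """Maps a parameter set to model outputs at observation time points.

    Simulates the chemostat steady state (warm-started from the shipped
    state) followed by ``n_cycles`` feast/famine cycles, then samples the
    last cycle at each observable's time points.  Raises on failure; the
    residual builder converts failures into finite penalty residuals.
    """

    def __init__(self, protocol: FeedProtocol, observables,
                 n_cycles: int = 1, sensing: bool = True,
                 glycogen: GlycogenTables | None = None,
                 rtol: float = 1e-6, atol: float = 1e-8,
                 warm_state: np.ndarray | None = None,
                 flux_nodes: np.ndarray | None = None):
        #: mapping (table, series) -> sorted time array
        self.observables = {k: np.asarray(t, float) for k, t in observables.items()}
        self.protocol = protocol
        self.n_cycles = n_cycles
        self.sensing = sensing
        self.glycogen = glycogen
        self.rtol = rtol
        self.atol = atol
        self.warm_state = warm_state
        # simulated fluxes are resampled piecewise-linearly through the same
        # node grid the synthetic generator uses, mirroring how node-based
        # flux estimates are compared against model rates
        if flux_nodes is None:
            from .synthetic import SyntheticSpec

            flux_nodes = SyntheticSpec.__dataclass_fields__["flux_nodes"].default_factory()
        self.flux_nodes = np.asarray(flux_nodes, float)
        self._needs_label = any(tab == "enrich" for tab, _ in self.observables)

    @classmethod
    def for_bundle(cls, bundle: ObservationBundle, protocol: FeedProtocol,
                   tables=("conc", "flux"), **kw) -> "CycleSimulator":
        obs = {}
        for tab in tables:
            df = bundle.table(tab)
            for key in df["series"].unique():
                obs[(tab, key)] = df[df["series"] == key]["time_s"].to_numpy()
        return cls(protocol, obs, **kw)

    def __call__(self, params: ParameterSet) -> dict:
        y_ss, model = run_chemostat(params, self.protocol, y0=self.warm_state,
                                    sensing=self.sensing, glycogen=self.glycogen,
                                    horizon_s=5e4)
        traj = run_cycles(y_ss, params, self.protocol, model=model,
                          n_cycles=self.n_cycles, t_res=2.0,
                          rtol=self.rtol, atol=self.atol)
        last = traj.cycle_mask(self.n_cycles - 1)
        tc = traj.cycle_time[last]
        etraj = None
        if self._needs_label:
            from .labeling import simulate_enrichment

            etraj = simulate_enrichment(traj.Y[-1], params, self.protocol,
                                        self.protocol.label_fraction,
                                        n_cycles=1, model=model,
                                        rtol=self.rtol, atol=self.atol)
        out = {}
        for (tab, key), times in self.observables.items():
            if tab == "conc":
                out[(tab, key)] = np.interp(times, tc, traj.species(key)[last])
            elif tab == "flux":
                node_v = np.interp(self.flux_nodes, tc, traj.flux(key)[last])
                out[(tab, key)] = np.interp(times, self.flux_nodes, node_v)
            elif tab == "enrich":
                out[(tab, key)] = np.interp(times, etraj.cycle_time,
                                            etraj.enrichment(key))
            else:
                raise KeyError(f"unknown observable table {tab!r}")
        return out


# ----------------------------------------------------------------------
# Residuals and objective
# ----------------------------------------------------------------------

def _apply_theta(config: EstimationConfig, theta_log10: np.ndarray) -> ParameterSet:
    updates = {name: 10.0 ** v for name, v in zip(config.free_names, theta_log10)}
    return config.reference.replace(updates, role="estimated")


def _weight_for(config: EstimationConfig, tab: str, key: str) -> float:
    return float(config.weights.get((tab, key), config.weights.get(tab, 1.0)))


def _data_block_size(data: ObservationBundle, simulator) -> int:
    return sum(len(t) for t in simulator.observables.values())


def build_residuals(theta_log10: np.ndarray, config: EstimationConfig,
                    data: ObservationBundle, simulator) -> np.ndarray:
    """Weighted, normalized data residuals plus L1 penalty residuals.

    Per observable series: ``w * (sim - obs) / norm`` with ``norm = max
    |obs|`` of that series (every metabolite contributes with the same
    weight before the explicit weighting factors).  With ``lam > 0`` one
    extra residual per free parameter, ``sqrt(lam * |log10 ref - theta|)``.
    A failed simulation yields finite penalty residuals, not an exception.
    """
    theta_log10 = np.asarray(theta_log10, dtype=float)
    n_data = _data_block_size(data, simulator)
    try:
        params = _apply_theta(config, theta_log10)
        sim = simulator(params)
        blocks = []
        for (tab, key), times in simulator.observables.items():
            obs_df = data.series(tab, key)
            obs = np.interp(times, obs_df["time_s"].to_numpy(),
                            obs_df["value"].to_numpy())
            norm = np.max(np.abs(obs))
            norm = norm if norm > 0 else 1.0
            w = _weight_for(config, tab, key)
            blocks.append(w * (sim[(tab, key)] - obs) / norm)
        r_data = np.concatenate(blocks) if blocks else np.zeros(0)
        if not np.all(np.isfinite(r_data)):
            raise FloatingPointError("non-finite simulated observables")
    except Exception:  # noqa: BLE001 - any failure becomes a penalty
        r_data = np.full(n_data, PENALTY_RESIDUAL)
    if config.lam > 0:
        ref = np.log10([config.reference[k] for k in config.free_names])
        pen = np.sqrt(config.lam * np.abs(ref - theta_log10))
        return np.concatenate([r_data, pen])
    return r_data


def objective_parts(theta_log10, config, data, simulator) -> tuple[float, float]:
    """(data error, parameter error) of the decomposed objective."""
    r = build_residuals(theta_log10, config, data, simulator)
    n_pen = len(config.free_names) if config.lam > 0 else 0
    r_data = r[: len(r) - n_pen] if n_pen else r
    data_err = float(np.sum(r_data**2))
    ref = np.log10([config.reference[k] for k in config.free_names])
    dev = float(np.sum(np.abs(ref - np.asarray(theta_log10))))
    return data_err, config.lam * dev


# ----------------------------------------------------------------------
# Fits
# ----------------------------------------------------------------------

def _default_simulator(config, data, protocol, sensing, glycogen, n_cycles,
                       simulator):
    if simulator is not None:
        return simulator
    if protocol is None:
        raise ValueError("either a simulator or a protocol is required")
    return CycleSimulator.for_bundle(data, protocol, sensing=sensing,
                                     glycogen=glycogen, n_cycles=n_cycles)


def fit_subset(config: EstimationConfig, data: ObservationBundle,
               simulator=None, protocol: FeedProtocol | None = None,
               sensing: bool = True, glycogen: GlycogenTables | None = None,
               n_cycles: int = 1) -> FitResult:
    """Bounded nonlinear least squares from the reference values.

    Multistart (``config.n_starts``) jitters the initial point around the
    reference in log10 space with a seeded generator; the best run wins.
    Non-convergence returns the best iterate flagged, not an exception.
    """
    simulator = _default_simulator(config, data, protocol, sensing, glycogen,
                                   n_cycles, simulator)
    if not config.free_names:
        theta = np.zeros(0)
        data_err, param_err = objective_parts(theta, config, data, simulator)
        return FitResult(
            estimate=config.reference.replace({}, role="estimated"),
            data_error=data_err, param_error=param_err, param_deviation=0.0,
            cost=data_err + param_err,
            residual=build_residuals(theta, config, data, simulator),
            success=True, message="no free parameters",
            subset_id="+".join(config.subset), weights=dict(config.weights))

    x_ref = np.log10([config.reference[k] for k in config.free_names])
    lo, hi = x_ref - config.bounds_decades, x_ref + config.bounds_decades
    rng = np.random.default_rng(config.seed)
    best = None
    for start in range(max(config.n_starts, 1)):
        x0 = x_ref.copy()
        if start > 0:
            x0 = np.clip(x_ref + rng.uniform(-config.start_jitter,
                                             config.start_jitter, len(x_ref)),
                         lo, hi)
        sol = least_squares(build_residuals, x0, bounds=(lo, hi),
                            args=(config, data, simulator), method="trf",
                            max_nfev=config.max_nfev, xtol=config.xtol,
                            ftol=config.ftol, diff_step=1e-3)
        if best is None or sol.cost < best.cost:
            best = sol
    data_err, param_err = objective_parts(best.x, config, data, simulator)
    dev = param_err / config.lam if config.lam > 0 else float(
        np.sum(np.abs(x_ref - best.x)))
    return FitResult(
        estimate=_apply_theta(config, best.x), data_error=data_err,
        param_error=param_err, param_deviation=dev,
        cost=data_err + param_err, residual=best.fun,
        success=bool(best.status > 0), message=best.message,
        subset_id="+".join(config.subset), weights=dict(config.weights),
        nfev=int(best.nfev))


# ----------------------------------------------------------------------
# Step 1: combinatorial screening
# ----------------------------------------------------------------------

def combinatorial_screen(subsets, weight_grids, data: ObservationBundle,
                         reference: ParameterSet,
                         protocol: FeedProtocol | None = None,
                         simulator=None, estimable: dict | None = None,
                         n_random: int = 0, random_pool=("PGI", "PFK"),
                         seed: int = 0, fit_options: dict | None = None,
                         sensing: bool = True,
                         glycogen: GlycogenTables | None = None) -> pd.DataFrame:
    """Fit every (subset x weight vector) and rank the outcomes.

    Every subset must contain the trehalose cycle; seeded random subsets
    (trehalose cycle plus a random draw from ``random_pool``) can be
    appended.  Ranking: cost ascending, ties broken by fewer enzymes, then
    lexicographic subset id.  Individual fit failures are recorded and the
    screen continues.
    """
    estimable = estimable if estimable is not None else ESTIMABLE_KEYS
    subsets = [tuple(s) for s in subsets]
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        extra = tuple(rng.choice(random_pool,
                                 size=rng.integers(1, len(random_pool) + 1),
                                 replace=False))
        subsets.append(tuple(TREHALOSE_CYCLE_REACTIONS) + extra)
    for sub in subsets:
        missing = set(TREHALOSE_CYCLE_REACTIONS) - set(sub)
        if missing:
            raise ValueError(
                f"subset {sub} lacks trehalose-cycle reactions {sorted(missing)}")
    rows = []
    for sub in subsets:
        free = tuple(f"{rxn}.{c}" for rxn in sub for c in estimable.get(rxn, ()))
        for wi, weights in enumerate(weight_grids):
            config = EstimationConfig(subset=sub, free_names=free,
                                      reference=reference, weights=dict(weights),
                                      seed=seed, **(fit_options or {}))
            try:
                fit = fit_subset(config, data, simulator=simulator,
                                 protocol=protocol, sensing=sensing,
                                 glycogen=glycogen)
                rows.append({
                    "subset_id": "+".join(sub), "n_enzymes": len(sub),
                    "weight_index": wi, "cost": fit.cost,
                    "data_error": fit.data_error, "success": fit.success,
                    "message": fit.message})
            except Exception as exc:  # noqa: BLE001
                rows.append({
                    "subset_id": "+".join(sub), "n_enzymes": len(sub),
                    "weight_index": wi, "cost": np.inf, "data_error": np.inf,
                    "success": False, "message": f"failed: {exc}"})
    table = pd.DataFrame(rows)
    table = table.sort_values(["cost", "n_enzymes", "subset_id"],
                              kind="mergesort").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


# ----------------------------------------------------------------------
# Step 2: regularization sweep
# ----------------------------------------------------------------------

def regularization_sweep(subset, lam_grid, data: ObservationBundle,
                         reference: ParameterSet,
                         protocol: FeedProtocol | None = None,
                         simulator=None, estimable: dict | None = None,
                         knee_factor: float = 1.05, knee_abs_tol: float = 1e-9,
                         fit_options: dict | None = None, seed: int = 0,
                         sensing: bool = True,
                         glycogen: GlycogenTables | None = None) -> dict:
    """Sweep lambda over a grid (must include 0) and pick the knee.

    The chosen lambda is the largest one whose data error stays within
    ``knee_factor`` of the minimum over the grid (plus a small absolute
    floor so the rule stays meaningful when the data can be fit exactly).
    Returns the curve table, the chosen lambda and the fit at the chosen
    lambda.
    """
    lam_grid = sorted(float(l) for l in lam_grid)
    if lam_grid[0] != 0.0:
        raise ValueError("lambda grid must include 0")
    estimable = estimable if estimable is not None else ESTIMABLE_KEYS
    free = tuple(f"{rxn}.{c}" for rxn in subset for c in estimable.get(rxn, ()))
    fits = {}
    rows = []
    for lam in lam_grid:
        config = EstimationConfig(subset=tuple(subset), free_names=free,
                                  reference=reference, lam=lam, seed=seed,
                                  **(fit_options or {}))
        fit = fit_subset(config, data, simulator=simulator, protocol=protocol,
                         sensing=sensing, glycogen=glycogen)
        fits[lam] = fit
        rows.append({"lam": lam, "data_error": fit.data_error,
                     "param_error": fit.param_error,
                     "param_deviation": fit.param_deviation,
                     "cost": fit.cost, "success": fit.success})
    curve = pd.DataFrame(rows)
    min_err = curve["data_error"].min()
    ok = curve[curve["data_error"] <= knee_factor * min_err + knee_abs_tol]
    lam_star = float(ok["lam"].max())
    return {"curve": curve, "lambda": lam_star, "fit": fits[lam_star],
            "fits": fits}


# ----------------------------------------------------------------------
# Reporting
# ----------------------------------------------------------------------

def fold_change_report(reference, estimated, threshold: float = 0.05,
                       include_all: bool = False) -> pd.DataFrame:
    """Fold changes (estimated / reference), rounded to two decimals.

    Parameters changing by less than ``threshold`` (fractionally) are
    omitted unless ``include_all``.  Keys present on only one side are
    reported as gaps (NaN fold change), not failures.
    """
    ref = dict(reference.values if isinstance(reference, ParameterSet)
               else reference)
    est = dict(estimated.values if isinstance(estimated, ParameterSet)
               else estimated)
    rows = []
    for key in sorted(set(ref) | set(est)):
        rxn, const = key.split(".", 1) if "." in key else (key, "")
        r, e = ref.get(key), est.get(key)
        if r is None or e is None:
            rows.append({"enzyme": rxn, "parameter": const, "reference": r,
                         "estimated": e, "fold_change": np.nan})
            continue
        if r == 0.0 and e == 0.0:
            continue
        fold = e / r if r != 0.0 else np.nan  # threshold switched on/off
        if not include_all and np.isfinite(fold) and abs(fold - 1.0) < threshold:
            continue
        rows.append({"enzyme": rxn, "parameter": const, "reference": r,
                     "estimated": e, "fold_change": round(fold, 2)})
    return pd.DataFrame(rows, columns=["enzyme", "parameter", "reference",
                                       "estimated", "fold_change"])
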