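"""Robustness ensembles and the passive-transport feasibility scan.

Two sampling experiments:

* ``perturb_ensemble`` — all kinetic constants jittered uniformly within a
  relative range (default 10%); per-time dispersion of every species and
  flux across the ensemble quantifies robustness of the cycle response.
* ``hxt_feasibility_scan`` — transporter constants drawn log-uniformly over
  several decades with the extracellular glucose trace pinned to a
  configured cycle profile; each sample is scored by its uptake at the
  feed-end peak (20 s) and at the cycle end (400 s).  The scan restates the
  negative result that purely passive kinetics cannot combine a high peak
  uptake with near-zero end-of-cycle uptake, while the sensing threshold
  configuration achieves both.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .model import GlycogenTables, YeastModel
from .params import ParameterSet
from .protocol import FeedProtocol, run_cycles

__all__ = [
    "EnsembleSpec",
    "EnsembleResult",
    "perturb_ensemble",
    "GlucoseTrace",
    "evaluate_uptake",
    "hxt_feasibility_scan",
]

#: Transporter constants randomized in the feasibility scan.
HXT_SCAN_KEYS = ("HXT.Vmax", "HXT.Km", "HXT.Ki")


@dataclass(frozen=True)
class EnsembleSpec:
    """Sampling plan for a perturbation ensemble or a decade scan."""

    n: int = 50
    rel_range: float = 0.10
    decades: float = 3.0
    seed: int = 0
    scope: str = "all"  # 'all' | 'hxt'

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.rel_range < 0 or self.decades <= 0:
            raise ValueError("ranges must be positive")
        if self.scope not in ("all", "hxt"):
            raise ValueError("scope must be 'all' or 'hxt'")


@dataclass
class EnsembleResult:
    times: np.ndarray
    species_names: list
    reaction_names: list
    conc_rsd: np.ndarray        # n_t x n_species, relative SD across samples
    flux_rsd: np.ndarray        # n_t x n_reactions
    n_ok: int
    n_failed: int
    sample_factors: np.ndarray  # n_ok x n_params

    @property
    def failure_rate(self) -> float:
        return self.n_failed / max(self.n_ok + self.n_failed, 1)

    def median_rsd(self) -> tuple[float, float]:
        """(median concentration RSD, median flux RSD) over time/variables."""
        return (float(np.nanmedian(self.conc_rsd)),
                float(np.nanmedian(self.flux_rsd)))


def _perturbed(params: ParameterSet, rng: np.random.Generator,
               rel_range: float, scope: str) -> tuple[ParameterSet, np.ndarray]:
    keys = [k for k in sorted(params.values)
            if scope == "all" or k.startswith("HXT.")]
    factors = rng.uniform(1.0 - rel_range, 1.0 + rel_range, len(keys))
    updates = {k: params[k] * f for k, f in zip(keys, factors)
               if params[k] != 0.0}
    return params.replace(updates), factors


def perturb_ensemble(params: ParameterSet, spec: EnsembleSpec,
                     protocol: FeedProtocol, base_state: np.ndarray,
                     sensing: bool = True,
                     glycogen: GlycogenTables | None = None,
                     n_cycles: int = 1, t_res: float = 4.0,
                     rtol: float = 1e-6, atol: float = 1e-8) -> EnsembleResult:
    """Cycle-response dispersion under uniform parameter jitter.

    All samples integrate the same number of cycles from ``base_state``
    (the calibrated chemostat steady state); failed samples are counted and
    excluded.
    """
    rng = np.random.default_rng(spec.seed)
    conc_stack, flux_stack, factor_rows = [], [], []
    n_failed = 0
    species_names = reaction_names = times = None
    for _ in range(spec.n):
        p_i, factors = _perturbed(params, rng, spec.rel_range, spec.scope)
        try:
            model = YeastModel(p_i, protocol.biomass_gdw_per_l,
                               protocol.vacuole_fraction, sensing=sensing,
                               glycogen=glycogen)
            traj = run_cycles(base_state, p_i, protocol, model=model,
                              n_cycles=n_cycles, t_res=t_res,
                              rtol=rtol, atol=atol)
        except Exception:  # noqa: BLE001
            n_failed += 1
            continue
        last = traj.cycle_mask(n_cycles - 1)
        conc_stack.append(traj.Y[last][:, : model.i_vol])
        flux_stack.append(traj.flux_table()[last])
        factor_rows.append(factors)
        if species_names is None:
            species_names = model.net.species_names
            reaction_names = model.net.reaction_names
            times = traj.cycle_time[last]
    if not conc_stack:
        raise RuntimeError("every ensemble sample failed to integrate")
    conc = np.stack(conc_stack)   # n_ok x n_t x n_species
    flux = np.stack(flux_stack)

    def rsd(a):
        mean = a.mean(axis=0)
        sd = a.std(axis=0)
        return sd / np.maximum(np.abs(mean), 1e-12)

    return EnsembleResult(times=times, species_names=species_names,
                          reaction_names=reaction_names,
                          conc_rsd=rsd(conc), flux_rsd=rsd(flux),
                          n_ok=len(conc_stack), n_failed=n_failed,
                          sample_factors=np.array(factor_rows))


# ----------------------------------------------------------------------
# Passive-transport feasibility scan
# ----------------------------------------------------------------------

@dataclass
class GlucoseTrace:
    """Prescribed extracellular glucose profile over one cycle."""

    times: np.ndarray
    glcec_mm: np.ndarray

    def __call__(self, t):
        return np.interp(t, self.times, self.glcec_mm)

    @classmethod
    def from_trajectory(cls, traj, cycle: int | None = None) -> "GlucoseTrace":
        c = traj.n_cycles - 1 if cycle is None else cycle
        m = traj.cycle_mask(c)
        return cls(traj.cycle_time[m].copy(), traj.species("GLCec")[m].copy())


def _resimulate_intracellular(model: YeastModel, base_state: np.ndarray,
                              trace: GlucoseTrace, protocol: FeedProtocol,
                              rtol=1e-6, atol=1e-8) -> np.ndarray:
    """One cycle with GLCec pinned to the trace; returns states at 1 s."""
    i_glc = model.i["GLCec"]

    def rhs(y, t):
        y = y.copy()
        y[i_glc] = trace(t)
        dy = model.rhs(y, t)
        dy[i_glc] = 0.0
        return dy

    tgrid = np.arange(0.0, protocol.cycle_s + 0.5, 1.0)
    y0 = np.asarray(base_state, dtype=float).copy()
    y0[i_glc] = trace(0.0)
    Y = odeint(rhs, y0, tgrid, rtol=rtol, atol=atol, mxstep=20000)
    Y[:, i_glc] = trace(tgrid)
    return tgrid, Y


def evaluate_uptake(params: ParameterSet, trace: GlucoseTrace,
                    protocol: FeedProtocol, base_state: np.ndarray,
                    sensing: bool, freeze_intracellular: bool = False,
                    glci_trace=None,
                    glycogen: GlycogenTables | None = None) -> tuple[float, float]:
    """Transporter rate at 20 s and 400 s under a fixed glucose trace.

    With ``freeze_intracellular`` the intracellular glucose follows the
    supplied ``glci_trace`` (no re-integration); otherwise the intracellular
    state is re-simulated per parameter sample.
    """
    model = YeastModel(params, protocol.biomass_gdw_per_l,
                       protocol.vacuole_fraction, sensing=sensing,
                       glycogen=glycogen)
    if freeze_intracellular:
        if glci_trace is None:
            raise ValueError("freeze_intracellular requires a glci_trace")
        out = []
        for t in (20.0, protocol.cycle_s):
            y = np.asarray(base_state, dtype=float).copy()
            y[model.i["GLCec"]] = trace(t)
            y[model.i["GLCi"]] = glci_trace(t)
            out.append(float(model.fluxes(y, t)[0]))
        return tuple(out)
    tgrid, Y = _resimulate_intracellular(model, base_state, trace, protocol)
    v20 = float(model.fluxes(Y[tgrid == 20.0][0], 20.0)[0])
    v400 = float(model.fluxes(Y[-1], protocol.cycle_s)[0])
    return v20, v400


def hxt_feasibility_scan(trace: GlucoseTrace, spec: EnsembleSpec,
                         params: ParameterSet, protocol: FeedProtocol,
                         base_state: np.ndarray, sensing: bool = False,
                         uptake_peak_req: float = 0.72,
                         uptake_end_eps: float = 0.02,
                         freeze_intracellular: bool = False, glci_trace=None,
                         glycogen: GlycogenTables | None = None) -> dict:
    """Log-uniform transporter-parameter scan under a pinned glucose trace.

    Per sample the transporter constants are drawn within ``spec.decades``
    decades around the estimates and the uptake pair (20 s, 400 s) is
    recorded.  The feasibility verdict asks whether any sample reaches the
    peak requirement while keeping the end-of-cycle uptake magnitude within
    ``uptake_end_eps`` ("almost zero"; negative values count as zero-like).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n):
        factors = 10.0 ** rng.uniform(-spec.decades, spec.decades,
                                      len(HXT_SCAN_KEYS))
        p_i = params.replace({k: params[k] * f
                              for k, f in zip(HXT_SCAN_KEYS, factors)})
        try:
            v20, v400 = evaluate_uptake(
                p_i, trace, protocol, base_state, sensing=sensing,
                freeze_intracellular=freeze_intracellular,
                glci_trace=glci_trace, glycogen=glycogen)
            ok = True
        except Exception:  # noqa: BLE001
            v20 = v400 = np.nan
            ok = False
        rows.append({"sample": i,
                     **{k: p_i[k] for k in HXT_SCAN_KEYS},
                     "uptake_20s": v20, "uptake_400s": v400,
                     "integrated": ok})
    table = pd.DataFrame(rows)
    hits = table[(table["uptake_20s"] >= uptake_peak_req)
                 & (table["uptake_400s"].abs() <= uptake_end_eps)]
    return {"table": table, "feasible": bool(len(hits)), "n_hits": int(len(hits)),
            "uptake_peak_req": uptake_peak_req, "uptake_end_eps": uptake_end_eps}
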