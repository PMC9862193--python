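"""13C labelled-fraction mass balances on top of the total model.

Each carbon species carries a secondary balance for its labelled
concentration.  Every reaction term of the total balance reappears,
multiplied by the enrichment (labelled/total) of the species the term
consumes; reversible reactions are split into non-negative forward and
backward fluxes first, so each direction carries its own substrate
enrichment.  Cofactors and phosphate carry no label.

The formalism tracks pool enrichment, not positional isotopomers: at the
aldolase cleavage both triose products inherit the FBP enrichment, and for
condensations (TPS1) the product enrichment is the carbon-weighted mean of
the substrate enrichments, which conserves labelled carbon exactly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .model import BoundaryFlow, YeastModel
from .network import Network

__all__ = [
    "split_reversible",
    "labelled_derivative",
    "make_joint_rhs",
    "ode_rhs_labelled",
    "simulate_enrichment",
    "enrichment_frame",
]


def split_reversible(v_net: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split net fluxes into (forward, backward), both >= 0.

    ``v_fwd - v_bwd`` reconstructs the net flux bitwise: exactly one of the
    pair is nonzero per reaction.
    """
    v_net = np.asarray(v_net, dtype=float)
    v_fwd = np.maximum(v_net, 0.0)
    v_bwd = np.maximum(-v_net, 0.0)
    return v_fwd, v_bwd


def enrichments(net: Network, y_species: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Labelled fraction per carbon species; defined as 0 for empty pools."""
    e = np.empty(net.n_labelled)
    for name, l in net.l_index.items():
        tot = y_species[net.s_index[name]]
        e[l] = L[l] / tot if tot > 1e-30 else 0.0
    return e


def labelled_derivative(net: Network, v_net: np.ndarray, y_species: np.ndarray,
                        L: np.ndarray, row_scale: np.ndarray | None = None) -> np.ndarray:
    """Assemble d(labelled)/dt for every carbon species.

    ``row_scale`` applies the same compartment volume-ratio scaling as the
    total balances (1 everywhere for single-compartment toy networks).
    """
    v_fwd, v_bwd = split_reversible(v_net)
    e = enrichments(net, y_species, L)
    dL = np.zeros(net.n_labelled)
    for j, table in enumerate(net._carbon_tables):
        cin, cout, in_carbons, out_carbons, denom_fwd, denom_bwd = table
        vf = v_fwd[j]
        if vf != 0.0 and (cin or cout):
            for l, c in cin:
                dL[l] -= vf * c * e[l]
            if cout and denom_fwd > 0:
                mix = sum(cn * e[l] for l, cn in in_carbons) / denom_fwd
                for l, c in cout:
                    dL[l] += vf * c * mix
        vb = v_bwd[j]
        if vb != 0.0 and (cin or cout):
            for l, c in cout:
                dL[l] -= vb * c * e[l]
            if cin and denom_bwd > 0:
                mix = sum(cn * e[l] for l, cn in out_carbons) / denom_bwd
                for l, c in cin:
                    dL[l] += vb * c * mix
    if row_scale is not None:
        for name, l in net.l_index.items():
            dL[l] *= row_scale[net.s_index[name]]
    return dL


def _flow_label_terms(model: YeastModel, flow: BoundaryFlow, y: np.ndarray,
                      L: np.ndarray, dL: np.ndarray) -> None:
    """Add feed/dilution terms for labelled extracellular species in place."""
    net = model.net
    l_glc = net.l_index["GLCec"]
    l_tre = net.l_index["TREec"]
    if flow.mode == "chemostat":
        d = flow.rate
        dL[l_glc] += d * (flow.label_frac * flow.conc - L[l_glc])
        dL[l_tre] += -d * L[l_tre]
    elif flow.mode == "feed":
        spec = flow.rate / y[model.i_vol]
        dL[l_glc] += spec * (flow.label_frac * flow.conc - L[l_glc])
        dL[l_tre] += -spec * L[l_tre]
    # outflow removes broth at bulk composition: no concentration change


def make_joint_rhs(model: YeastModel, flow: BoundaryFlow, label_frac: float):
    """RHS for the stacked state ``[totals, labelled]``."""
    n_tot = model.n_states
    net = model.net
    scale = model._row_scale
    flow = BoundaryFlow(flow.mode, flow.rate, flow.conc, label_frac)

    def rhs(yy, t):
        y = yy[:n_tot]
        L = yy[n_tot:]
        v = model.fluxes(y, t)
        dy = np.empty(len(yy))
        dy[: model.i_vol] = model._S_scaled @ v
        dy[model.i_vol] = 0.0
        i_glc, i_tre = model.i["GLCec"], model.i["TREec"]
        if flow.mode == "chemostat":
            dy[i_glc] += flow.rate * (flow.conc - y[i_glc])
            dy[i_tre] += -flow.rate * y[i_tre]
        elif flow.mode == "feed":
            spec = flow.rate / y[model.i_vol]
            dy[i_glc] += spec * (flow.conc - y[i_glc])
            dy[i_tre] += -spec * y[i_tre]
            dy[model.i_vol] = flow.rate
        elif flow.mode == "outflow":
            dy[model.i_vol] = -flow.rate
        dL = labelled_derivative(net, v, y, L, scale)
        _flow_label_terms(model, flow, y, L, dL)
        dy[n_tot:] = dL
        return dy

    return rhs


def ode_rhs_labelled(state: np.ndarray, lstate: np.ndarray, t: float,
                     params, protocol, label_fraction_feed: float,
                     sensing: bool = True) -> np.ndarray:
    """d(labelled)/dt at a given total state and cycle time.

    The protocol phase is inferred from ``t`` modulo the cycle length, as in
    :func:`yeastff.model.ode_rhs_total`.
    """
    if not 0.0 <= label_fraction_feed <= 1.0:
        raise ValueError("label fraction must lie in [0, 1]")
    model = YeastModel(params, protocol.biomass_gdw_per_l,
                       protocol.vacuole_fraction, sensing=sensing)
    flow = protocol.flow_at(t % protocol.cycle_s, state[-1], label_fraction_feed)
    v = model.fluxes(np.asarray(state, float), t)
    dL = labelled_derivative(model.net, v, np.asarray(state, float),
                             np.asarray(lstate, float), model._row_scale)
    _flow_label_terms(model, flow, np.asarray(state, float),
                      np.asarray(lstate, float), dL)
    return dL


def simulate_enrichment(post_cycle_state: np.ndarray, params, protocol,
                        label_fraction: float = 0.99, n_cycles: int = 1,
                        model: YeastModel | None = None, t_res: float = 1.0,
                        rtol: float | None = None, atol: float | None = None):
    """Run labelled cycles from the end state of the unlabelled regime.

    Feed glucose enters with the given labelled fraction; all pools start
    unlabelled.  Returns a :class:`yeastff.protocol.Trajectory` whose
    ``enrichment`` accessor yields percent profiles over cycle time.

    Raises if the labelled fraction of any pool leaves [0, 1] beyond the
    integrator tolerance.
    """
    from .protocol import run_cycles

    traj = run_cycles(post_cycle_state, params, protocol, model=model,
                      n_cycles=n_cycles, t_res=t_res,
                      label_frac=label_fraction, rtol=rtol, atol=atol)
    tol = 1e-8
    for name in traj.model.net.labelled_names:
        lab = traj.labelled(name)
        tot = traj.species(name)
        if np.any(lab < -tol) or np.any(lab > tot + tol):
            raise RuntimeError(f"labelled fraction of {name} left [0, 1]")
    return traj


def enrichment_frame(traj) -> pd.DataFrame:
    """Tidy (species, time_s, enrichment_percent) table."""
    rows = []
    for name in traj.model.net.labelled_names:
        rows.append(pd.DataFrame({
            "species": name,
            "time_s": traj.times,
            "enrichment_percent": traj.enrichment(name),
        }))
    return pd.concat(rows, ignore_index=True)
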