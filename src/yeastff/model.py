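"""Total-concentration kinetic model: flux evaluation and ODE right-hand side.

The state vector layout follows :data:`yeastff.network.SPECIES` with the
broth volume (L) appended as the last entry.  Boundary exchange (chemostat
dilution, block-wise feeding, outflow) is described by a
:class:`BoundaryFlow` so that the protocol runner can integrate each phase
without any solver step straddling a flow discontinuity.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import ratelaws as rl
from .constants import BIOMASS_SPECIFIC_VOLUME_L_PER_GDW
from .network import (
    ADENYLATE_MOIETY,
    NICOTINAMIDE_MOIETY,
    Network,
    yeast_network,
)
from .params import ParameterSet

__all__ = [
    "BoundaryFlow",
    "GlycogenTables",
    "YeastModel",
    "state_from_dict",
    "state_to_dict",
    "load_chemostat_state",
    "ode_rhs_total",
]


class RateEvaluationError(RuntimeError):
    """A rate law produced a non-finite value; carries the reaction name."""


@dataclass(frozen=True)
class BoundaryFlow:
    """Exchange with the environment during one protocol phase.

    mode:
        ``"chemostat"`` (continuous in/out at dilution ``rate`` in s^-1),
        ``"feed"`` (volumetric inflow ``rate`` in L s^-1, no outflow),
        ``"outflow"`` (volumetric outflow ``rate`` in L s^-1, no inflow),
        or ``"batch"`` (closed).
    conc:
        Glucose concentration of the incoming stream (mM); ignored for
        outflow/batch.
    label_frac:
        Fraction of incoming glucose that is 13C labelled.
    """

    mode: str = "batch"
    rate: float = 0.0
    conc: float = 0.0
    label_frac: float = 0.0


BATCH = BoundaryFlow()


@dataclass
class GlycogenTables:
    """Piecewise-linear flux tables for glycogen synthesis and degradation.

    Times in s over one cycle, fluxes in mM s^-1 (cytosolic basis).  The
    chemostat phase uses the cycle-average of each table (a cycle-time
    profile has no meaning at steady state).
    """

    t_syn: np.ndarray
    v_syn: np.ndarray
    t_deg: np.ndarray
    v_deg: np.ndarray
    period: float = 400.0

    def __post_init__(self):
        self.t_syn = np.asarray(self.t_syn, dtype=float)
        self.v_syn = np.asarray(self.v_syn, dtype=float)
        self.t_deg = np.asarray(self.t_deg, dtype=float)
        self.v_deg = np.asarray(self.v_deg, dtype=float)
        self.syn_mean = float(np.trapezoid(self.v_syn, self.t_syn) / (self.t_syn[-1] - self.t_syn[0]))
        self.deg_mean = float(np.trapezoid(self.v_deg, self.t_deg) / (self.t_deg[-1] - self.t_deg[0]))

    @classmethod
    def from_csv(cls, syn_path, deg_path, period=400.0) -> "GlycogenTables":
        def read(path):
            ts, vs = [], []
            with open(path) as fh:
                for row in csv.DictReader(fh):
                    ts.append(float(row["time_s"]))
                    vs.append(float(row["flux_mM_per_s"]))
            return np.array(ts), np.array(vs)

        t_s, v_s = read(syn_path)
        t_d, v_d = read(deg_path)
        return cls(t_s, v_s, t_d, v_d, period)

    @classmethod
    def shipped(cls) -> "GlycogenTables":
        data = resources.files("yeastff.data")
        return cls.from_csv(
            data.joinpath("glycogen_synthesis.csv"),
            data.joinpath("glycogen_degradation.csv"),
        )

    @classmethod
    def zero(cls, period=400.0) -> "GlycogenTables":
        z = np.array([0.0, 0.0])
        t = np.array([0.0, period])
        return cls(t, z, t, z, period)

    def scaled(self, syn_factor: float, deg_factor: float) -> "GlycogenTables":
        return GlycogenTables(self.t_syn, self.v_syn * syn_factor,
                              self.t_deg, self.v_deg * deg_factor, self.period)


class YeastModel:
    """Flux and RHS evaluator for a fixed parameter set.

    Parameters
    ----------
    params:
        Kinetic constants.
    biomass_gdw_per_l:
        Biomass concentration in the broth (constant within cycles).
    vacuole_fraction:
        Vacuole volume as a fraction of cell volume.
    sensing:
        Whether the extracellular-glucose threshold in the transporter law
        is active.
    glycogen:
        Flux interpolation tables; defaults to the shipped calibrated ones.
    """

    def __init__(self, params: ParameterSet, biomass_gdw_per_l: float = 12.0,
                 vacuole_fraction: float = 0.10, sensing: bool = True,
                 glycogen: GlycogenTables | None = None):
        self.p = params
        self.net: Network = yeast_network()
        self.sensing = bool(sensing)
        self.glycogen = glycogen if glycogen is not None else GlycogenTables.shipped()
        self.biomass = float(biomass_gdw_per_l)
        self.vacuole_fraction = float(vacuole_fraction)
        cell_frac = self.biomass * BIOMASS_SPECIFIC_VOLUME_L_PER_GDW
        #: cytosol volume per broth volume
        self.phi_cyt = cell_frac * (1.0 - self.vacuole_fraction)
        #: cytosol-to-vacuole volume ratio
        self.cyt_over_vac = (1.0 - self.vacuole_fraction) / self.vacuole_fraction

        net = self.net
        self.i = {name: net.s_index[name] for name in net.species_names}
        self.i_vol = len(net.species_names)
        self.n_states = self.i_vol + 1
        # per-species compartment scale applied to S @ v
        scale = np.ones(len(net.species_names))
        for name, comp in net.compartment.items():
            if comp == "vac":
                scale[net.s_index[name]] = self.cyt_over_vac
            elif comp == "ec":
                scale[net.s_index[name]] = self.phi_cyt
        self._row_scale = scale
        self._S_scaled = net.S * scale[:, None]
        self.adenylate_vec = net.moiety_vector(ADENYLATE_MOIETY)
        self.nicotinamide_vec = net.moiety_vector(NICOTINAMIDE_MOIETY)
        self._extract_params()

    # ------------------------------------------------------------------
    def _extract_params(self) -> None:
        p = self.p
        self._k = {key: float(val) for key, val in p.values.items()}

    def with_params(self, params: ParameterSet) -> "YeastModel":
        return YeastModel(params, self.biomass, self.vacuole_fraction,
                          self.sensing, self.glycogen)

    # ------------------------------------------------------------------
    def fluxes(self, y: np.ndarray, t: float, chemostat_mode: bool = False) -> np.ndarray:
        """Net reaction rates (mM s^-1, cytosolic basis) at state ``y``."""
        k = self._k
        i = self.i
        yc = np.maximum(y[: self.i_vol], 0.0)  # guard solver undershoot
        GLCi, G6P, F6P, FBP = yc[i["GLCi"]], yc[i["G6P"]], yc[i["F6P"]], yc[i["FBP"]]
        DHAP, GAP, BPG = yc[i["DHAP"]], yc[i["GAP"]], yc[i["BPG"]]
        P3G, P2G, PEP, PYR = yc[i["P3G"]], yc[i["P2G"]], yc[i["PEP"]], yc[i["PYR"]]
        ACE, G1P, UDPG, T6P = yc[i["ACE"]], yc[i["G1P"]], yc[i["UDPG"]], yc[i["T6P"]]
        TREc, G3P, GLYCO = yc[i["TREc"]], yc[i["G3P"]], yc[i["GLYCO"]]
        ATP, ADP, AMP = yc[i["ATP"]], yc[i["ADP"]], yc[i["AMP"]]
        NAD, NADH, PI = yc[i["NAD"]], yc[i["NADH"]], yc[i["PI"]]
        TREv, GLCec, TREec = yc[i["TREv"]], yc[i["GLCec"]], yc[i["TREec"]]

        gly = self.glycogen
        if chemostat_mode:
            # a cycle-time profile has no meaning at steady state: use the
            # configured constant bases instead of the tables
            v_syn_base = k["GLYS.v_chemostat"]
            v_deg_base = k["GLYD.v_chemostat"]
        else:
            tc = t % gly.period
            v_syn_base = np.interp(tc, gly.t_syn, gly.v_syn)
            v_deg_base = np.interp(tc, gly.t_deg, gly.v_deg)

        v = np.empty(self.net.n_reactions)
        v[0] = rl.rate_hxt(GLCec, GLCi, k["HXT.Vmax"], k["HXT.Km"], k["HXT.Ki"],
                           k["HXT.Keq"], k["HXT.GLCec_min"], self.sensing)
        # hexose phosphorylation with competitive T6P inhibition on the
        # glucose site and MM saturation in ATP
        v[1] = (k["GLK.Vmax"] * (GLCi / (k["GLK.Km_GLC"] * (1.0 + T6P / k["GLK.Ki_T6P"]) + GLCi))
                * ATP / (k["GLK.Km_ATP"] + ATP))
        v[2] = rl.rate_mm_rev(G6P, F6P, k["PGI.Vmax"], k["PGI.Km_G6P"],
                              k["PGI.Km_F6P"], k["PGI.Keq"])
        v[3] = rl.rate_pfk(F6P, ATP, AMP, k["PFK.Vmax"], k["PFK.Km_F6P"],
                           k["PFK.Km_ATP"], k["PFK.n"], k["PFK.L0"],
                           k["PFK.Ki_ATP"], k["PFK.Ka_AMP"])
        # aldolase: reversible uni-bi
        kf, kd, kg = k["FBA.Km_FBP"], k["FBA.Km_DHAP"], k["FBA.Km_GAP"]
        v[4] = (k["FBA.Vmax"] / kf) * (FBP - DHAP * GAP / k["FBA.Keq"]) / (
            1.0 + FBP / kf + DHAP / kd + GAP / kg + DHAP * GAP / (kd * kg))
        v[5] = rl.rate_mm_rev(DHAP, GAP, k["TPI.Vmax"], k["TPI.Km_DHAP"],
                              k["TPI.Km_GAP"], k["TPI.Keq"])
        v[6] = rl.rate_rev_bibi(GAP, NAD, BPG, NADH, k["GAPDH.Vmax"],
                                k["GAPDH.Km_GAP"], k["GAPDH.Km_NAD"],
                                k["GAPDH.Km_BPG"], k["GAPDH.Km_NADH"],
                                k["GAPDH.Keq"]) * PI / (k["GAPDH.Km_PI"] + PI)
        v[7] = rl.rate_rev_bibi(BPG, ADP, P3G, ATP, k["PGK.Vmax"],
                                k["PGK.Km_BPG"], k["PGK.Km_ADP"],
                                k["PGK.Km_P3G"], k["PGK.Km_ATP"], k["PGK.Keq"])
        v[8] = rl.rate_mm_rev(P3G, P2G, k["GPM.Vmax"], k["GPM.Km_P3G"],
                              k["GPM.Km_P2G"], k["GPM.Keq"])
        v[9] = rl.rate_mm_rev(P2G, PEP, k["ENO.Vmax"], k["ENO.Km_P2G"],
                              k["ENO.Km_PEP"], k["ENO.Keq"])
        v[10] = rl.rate_pyk(PEP, ADP, FBP, k["PYK.Vmax"], k["PYK.K05_PEP"],
                            k["PYK.n"], k["PYK.Ka_FBP"], k["PYK.Km_ADP"])
        v[11] = rl.rate_hill(PYR, k["PDC.Vmax"], k["PDC.K05_PYR"], k["PDC.n"])
        v[12] = rl.rate_mm_irrev_bi(ACE, NADH, k["ADH.Vmax"], k["ADH.Km_ACE"],
                                    k["ADH.Km_NADH"])
        v[13] = rl.rate_mm_irrev_bi(DHAP, NADH, k["G3PDH.Vmax"],
                                    k["G3PDH.Km_DHAP"], k["G3PDH.Km_NADH"])
        v[14] = rl.rate_mm_irrev(G3P, k["GPP.Vmax"], k["GPP.Km_G3P"])
        v[15] = rl.rate_mm_rev(G1P, G6P, k["PGM1.Vmax"], k["PGM1.Km_G1P"],
                               k["PGM1.Km_G6P"], k["PGM1.Keq"])
        v[16] = rl.rate_ugp(G1P, ATP, UDPG, PI, k["UGP.Vmax"], k["UGP.Km_G1P"],
                            k["UGP.Km_ATP"], k["UGP.Km_UDPG"], k["UGP.Ki_G1P"],
                            k["UGP.Keq"])
        v[17] = rl.rate_mm_irrev_bi(G6P, UDPG, k["TPS1.Vmax"], k["TPS1.Km_G6P"],
                                    k["TPS1.Km_UDPG"])
        v[18] = rl.rate_mm_irrev(T6P, k["TPS2.Vmax"], k["TPS2.Km_T6P"])
        v[19] = rl.rate_mm_irrev(TREc, k["NTH1.Vmax"], k["NTH1.Km_TRE"])
        v[20] = rl.rate_mm_rev(TREc, TREec, k["AGT1.Vmax"], k["AGT1.Km_TREc"],
                               k["AGT1.Km_TREec"], k["AGT1.Keq"],
                               inhibitor=T6P, ki=k["AGT1.Ki_T6P"])
        v[21] = rl.rate_mm_rev(TREc, TREv, k["VACT.Vmax"], k["VACT.Km_TREc"],
                               k["VACT.Km_TREv"], k["VACT.Keq"])
        v[22] = rl.rate_mm_irrev(TREv, k["ATH1.Vmax"], k["ATH1.Km_TREv"],
                                 inhibitor=T6P, ki=k["ATH1.Ki_T6P"])
        v[23] = v_syn_base * UDPG / (UDPG + k["GLYS.Ksat_UDPG"])
        v[24] = v_deg_base * GLYCO / (GLYCO + k["GLYD.Ksat_GLY"])
        v[25] = k["ATPASE.k"] * ATP
        v[26] = rl.rate_adk(ATP, ADP, AMP, k["ADK.k"], k["ADK.Keq"])
        v[27] = rl.rate_mm_irrev(NADH, k["MITONADH.Vmax"], k["MITONADH.Km_NADH"])
        v[28] = rl.rate_mm_irrev(G6P, k["SINKG6P.Vmax"], k["SINKG6P.Km"])
        v[29] = rl.rate_mm_irrev(P3G, k["SINKP3G.Vmax"], k["SINKP3G.Km"])
        v[30] = k["SINKPYR.factor"] * rl.rate_mm_irrev(PYR, k["SINKPYR.Vmax"],
                                                       k["SINKPYR.Km"])
        v[31] = rl.rate_mm_irrev(ACE, k["SINKACE.Vmax"], k["SINKACE.Km"])
        v[32] = k["PIBUF.k"] * (k["PIBUF.PI_ref"] - PI)
        return v

    def diagnose_fluxes(self, y, t, chemostat_mode=False):
        """Evaluate fluxes and raise :class:`RateEvaluationError` naming the
        first reaction whose rate is non-finite."""
        v = self.fluxes(y, t, chemostat_mode)
        bad = np.flatnonzero(~np.isfinite(v))
        if bad.size:
            name = self.net.reaction_names[bad[0]]
            raise RateEvaluationError(f"non-finite rate in reaction {name}")
        return v

    # ------------------------------------------------------------------
    def rhs(self, y: np.ndarray, t: float, flow: BoundaryFlow = BATCH,
            chemostat_mode: bool = False) -> np.ndarray:
        """Time derivative of the total-concentration state."""
        v = self.fluxes(y, t, chemostat_mode)
        dy = np.empty(self.n_states)
        dy[: self.i_vol] = self._S_scaled @ v
        dy[self.i_vol] = 0.0
        i_glc, i_tre = self.i["GLCec"], self.i["TREec"]
        if flow.mode == "chemostat":
            d = flow.rate
            dy[i_glc] += d * (flow.conc - y[i_glc])
            dy[i_tre] += -d * y[i_tre]
        elif flow.mode == "feed":
            vol = y[self.i_vol]
            spec = flow.rate / vol
            dy[i_glc] += spec * (flow.conc - y[i_glc])
            dy[i_tre] += -spec * y[i_tre]
            dy[self.i_vol] = flow.rate
        elif flow.mode == "outflow":
            dy[self.i_vol] = -flow.rate
        return dy

    def rhs_per_reaction(self, y, t, flow: BoundaryFlow = BATCH,
                         chemostat_mode: bool = False) -> np.ndarray:
        """Independent reaction-by-reaction assembly (oracle for tests)."""
        v = self.fluxes(y, t, chemostat_mode)
        dy = np.zeros(self.n_states)
        for j, rxn in enumerate(self.net.reactions):
            for name, coeff in rxn.stoich.items():
                idx = self.i[name]
                dy[idx] += self._row_scale[idx] * coeff * v[j]
        flow_only = self.rhs(np.asarray(y, dtype=float), t, flow, chemostat_mode) \
            - self.rhs(np.asarray(y, dtype=float), t, BATCH, chemostat_mode)
        return dy + flow_only

    # ------------------------------------------------------------------
    def moiety_totals(self, y) -> tuple[float, float]:
        ys = np.asarray(y)[..., : self.i_vol]
        return float(ys @ self.adenylate_vec), float(ys @ self.nicotinamide_vec)


# ----------------------------------------------------------------------
# State helpers
# ----------------------------------------------------------------------

def state_from_dict(values: dict[str, float], volume: float | None = None) -> np.ndarray:
    """Build a state vector from a name->concentration mapping.

    The mapping may carry ``"VOL"``; otherwise ``volume`` must be given.
    """
    net = yeast_network()
    y = np.zeros(len(net.species_names) + 1)
    for name, val in values.items():
        if name == "VOL":
            y[-1] = float(val)
            continue
        y[net.s_index[name]] = float(val)
    if volume is not None:
        y[-1] = float(volume)
    if y[-1] <= 0:
        raise ValueError("broth volume must be > 0")
    return y


def state_to_dict(y: np.ndarray) -> dict[str, float]:
    net = yeast_network()
    out = {name: float(y[idx]) for name, idx in net.s_index.items()}
    out["VOL"] = float(y[-1])
    return out


def load_chemostat_state(which: str = "calibrated") -> np.ndarray:
    """Shipped chemostat steady-state vector for the calibrated or the
    reference parameter set."""
    fname = {"calibrated": "state_chemostat.json",
             "reference": "state_chemostat_reference.json"}[which]
    path = resources.files("yeastff.data").joinpath(fname)
    with open(path) as fh:
        return state_from_dict(json.load(fh))


def ode_rhs_total(state: np.ndarray, t: float, params: ParameterSet, protocol,
                  sensing: bool = True) -> np.ndarray:
    """Convenience RHS with the protocol phase inferred from cycle time.

    ``protocol`` is a :class:`yeastff.protocol.FeedProtocol`.  Inside the
    perturbation regime the phase at ``t`` (mod cycle length) selects
    feed / outflow / batch boundary terms.
    """
    model = YeastModel(params, protocol.biomass_gdw_per_l,
                       protocol.vacuole_fraction, sensing=sensing)
    flow = protocol.flow_at(t % protocol.cycle_s, state[-1])
    return model.rhs(np.asarray(state, dtype=float), t, flow)
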