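"""Network topology: species, reactions, stoichiometry and carbon maps.

The metabolic network covers glycolysis, the glycerol branch, the complete
trehalose cycle (cytosolic, vacuolar and extracellular trehalose), glycogen
synthesis/degradation, cofactor metabolism and lumped sink reactions toward
PPP/TCA/biomass.  Species concentrations are mM; the state vector also
carries the broth volume (L) as its last entry.

Compartments: ``cyt`` (cytosol), ``vac`` (vacuole), ``ec`` (extracellular).
Stoichiometric coefficients are written on the cytosolic-volume basis; the
RHS assembly in :mod:`yeastff.model` rescales rows of non-cytosolic species
by the appropriate volume ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Species", "Reaction", "Network", "yeast_network", "SPECIES", "REACTIONS"]


@dataclass(frozen=True)
class Species:
    name: str
    carbons: int
    compartment: str  # 'cyt' | 'vac' | 'ec' | 'none'


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry plus carbon-transfer bookkeeping.

    ``carbon_in`` / ``carbon_out`` give the molar coefficients of tracked
    carbon substrates/products for the forward direction; label flowing to
    untracked products (CO2, ethanol, glycerol, biomass sinks) is accounted
    for by ``extra_out_carbons`` (carbon atoms per turnover).
    """

    name: str
    stoich: dict[str, float]
    reversible: bool
    carbon_in: dict[str, float] = field(default_factory=dict)
    carbon_out: dict[str, float] = field(default_factory=dict)
    extra_out_carbons: float = 0.0


# ---------------------------------------------------------------------------
# Species (order defines the state-vector layout; VOL is appended last)
# ---------------------------------------------------------------------------
SPECIES: tuple[Species, ...] = (
    Species("GLCi", 6, "cyt"),
    Species("G6P", 6, "cyt"),
    Species("F6P", 6, "cyt"),
    Species("FBP", 6, "cyt"),
    Species("DHAP", 3, "cyt"),
    Species("GAP", 3, "cyt"),
    Species("BPG", 3, "cyt"),
    Species("P3G", 3, "cyt"),
    Species("P2G", 3, "cyt"),
    Species("PEP", 3, "cyt"),
    Species("PYR", 3, "cyt"),
    Species("ACE", 2, "cyt"),
    Species("G1P", 6, "cyt"),
    Species("UDPG", 6, "cyt"),
    Species("T6P", 12, "cyt"),
    Species("TREc", 12, "cyt"),
    Species("G3P", 3, "cyt"),
    Species("GLYCO", 6, "cyt"),   # glucose-equivalent units
    Species("ATP", 0, "cyt"),
    Species("ADP", 0, "cyt"),
    Species("AMP", 0, "cyt"),
    Species("NAD", 0, "cyt"),
    Species("NADH", 0, "cyt"),
    Species("PI", 0, "cyt"),
    Species("TREv", 12, "vac"),
    Species("GLCec", 6, "ec"),
    Species("TREec", 12, "ec"),
)

#: Name of the broth-volume pseudo-state appended after all species.
VOLUME_STATE = "VOL"


def _rx(name, stoich, reversible, cin=None, cout=None, extra=0.0):
    return Reaction(name, stoich, reversible, cin or {}, cout or {}, extra)


# ---------------------------------------------------------------------------
# Reactions (order defines the flux-vector layout)
# ---------------------------------------------------------------------------
REACTIONS: tuple[Reaction, ...] = (
    _rx("HXT", {"GLCec": -1, "GLCi": 1}, True, {"GLCec": 1}, {"GLCi": 1}),
    _rx("GLK", {"GLCi": -1, "ATP": -1, "G6P": 1, "ADP": 1}, False,
        {"GLCi": 1}, {"G6P": 1}),
    _rx("PGI", {"G6P": -1, "F6P": 1}, True, {"G6P": 1}, {"F6P": 1}),
    _rx("PFK", {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1}, False,
        {"F6P": 1}, {"FBP": 1}),
    _rx("FBA", {"FBP": -1, "DHAP": 1, "GAP": 1}, True,
        {"FBP": 1}, {"DHAP": 1, "GAP": 1}),
    _rx("TPI", {"DHAP": -1, "GAP": 1}, True, {"DHAP": 1}, {"GAP": 1}),
    _rx("GAPDH", {"GAP": -1, "NAD": -1, "PI": -1, "BPG": 1, "NADH": 1}, True,
        {"GAP": 1}, {"BPG": 1}),
    _rx("PGK", {"BPG": -1, "ADP": -1, "P3G": 1, "ATP": 1}, True,
        {"BPG": 1}, {"P3G": 1}),
    _rx("GPM", {"P3G": -1, "P2G": 1}, True, {"P3G": 1}, {"P2G": 1}),
    _rx("ENO", {"P2G": -1, "PEP": 1}, True, {"P2G": 1}, {"PEP": 1}),
    _rx("PYK", {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1}, False,
        {"PEP": 1}, {"PYR": 1}),
    # decarboxylation: one carbon leaves as CO2
    _rx("PDC", {"PYR": -1, "ACE": 1}, False, {"PYR": 1}, {"ACE": 1}, extra=1.0),
    # ethanol is not tracked: both acetaldehyde carbons leave the model
    _rx("ADH", {"ACE": -1, "NADH": -1, "NAD": 1}, False, {"ACE": 1}, {}, extra=2.0),
    _rx("G3PDH", {"DHAP": -1, "NADH": -1, "G3P": 1, "NAD": 1}, False,
        {"DHAP": 1}, {"G3P": 1}),
    # glycerol is secreted and not tracked
    _rx("GPP", {"G3P": -1, "PI": 1}, False, {"G3P": 1}, {}, extra=3.0),
    _rx("PGM1", {"G1P": -1, "G6P": 1}, True, {"G1P": 1}, {"G6P": 1}),
    _rx("UGP", {"G1P": -1, "ATP": -1, "UDPG": 1, "ADP": 1, "PI": 1}, True,
        {"G1P": 1}, {"UDPG": 1}),
    _rx("TPS1", {"G6P": -1, "UDPG": -1, "T6P": 1}, False,
        {"G6P": 1, "UDPG": 1}, {"T6P": 1}),
    _rx("TPS2", {"T6P": -1, "TREc": 1, "PI": 1}, False, {"T6P": 1}, {"TREc": 1}),
    _rx("NTH1", {"TREc": -1, "GLCi": 2}, False, {"TREc": 1}, {"GLCi": 2}),
    _rx("AGT1", {"TREc": -1, "TREec": 1}, True, {"TREc": 1}, {"TREec": 1}),
    _rx("VACT", {"TREc": -1, "TREv": 1}, True, {"TREc": 1}, {"TREv": 1}),
    _rx("ATH1", {"TREv": -1, "GLCi": 2}, False, {"TREv": 1}, {"GLCi": 2}),
    _rx("GLYS", {"UDPG": -1, "GLYCO": 1}, False, {"UDPG": 1}, {"GLYCO": 1}),
    _rx("GLYD", {"GLYCO": -1, "PI": -1, "G1P": 1}, False, {"GLYCO": 1}, {"G1P": 1}),
    _rx("ATPASE", {"ATP": -1, "ADP": 1, "PI": 1}, False),
    _rx("ADK", {"ADP": -2, "ATP": 1, "AMP": 1}, True),
    _rx("MITONADH", {"NADH": -1, "NAD": 1}, False),
    _rx("SINKG6P", {"G6P": -1}, False, {"G6P": 1}, {}, extra=6.0),
    _rx("SINKP3G", {"P3G": -1}, False, {"P3G": 1}, {}, extra=3.0),
    _rx("SINKPYR", {"PYR": -1}, False, {"PYR": 1}, {}, extra=3.0),
    _rx("SINKACE", {"ACE": -1}, False, {"ACE": 1}, {}, extra=2.0),
    # phosphate exchange with a buffered (polyphosphate-like) pool; signed
    _rx("PIBUF", {"PI": 1}, True),
)


class Network:
    """Species/reaction container with precomputed index structures.

    Generic over the species and reaction lists so that small toy networks
    can reuse the same stoichiometric and labelling machinery in tests.
    """

    def __init__(self, species: tuple[Species, ...], reactions: tuple[Reaction, ...],
                 volume_state: bool = True):
        self.species = species
        self.reactions = reactions
        self.species_names = [s.name for s in species]
        self.reaction_names = [r.name for r in reactions]
        self.has_volume = volume_state
        self.n_species = len(species) + (1 if volume_state else 0)
        self.n_reactions = len(reactions)
        self.s_index = {s.name: i for i, s in enumerate(species)}
        self.r_index = {r.name: i for i, r in enumerate(reactions)}
        self.carbons = {s.name: s.carbons for s in species}
        self.compartment = {s.name: s.compartment for s in species}
        # labelled sub-state: carbon species only, in species order
        self.labelled_names = [s.name for s in species if s.carbons > 0]
        self.l_index = {n: i for i, n in enumerate(self.labelled_names)}
        self.n_labelled = len(self.labelled_names)
        # dense stoichiometric matrix (species rows only, no volume row)
        S = np.zeros((len(species), self.n_reactions))
        for j, r in enumerate(reactions):
            for name, coeff in r.stoich.items():
                S[self.s_index[name], j] = coeff
        self.S = S
        self.reversible = np.array([r.reversible for r in reactions])
        self._carbon_tables = [self._carbon_table(r) for r in reactions]

    def _carbon_table(self, r: Reaction):
        """Precompute label-transfer index tables for both flux directions.

        Returns ``(cin, cout, in_carbons, out_carbons, denom_fwd,
        denom_bwd)`` where ``denom_fwd`` counts all product carbons per
        turnover (tracked plus untracked) and ``denom_bwd`` all substrate
        carbons (the product side of the reverse direction).
        """
        cin = [(self.l_index[n], c) for n, c in r.carbon_in.items()]
        cout = [(self.l_index[n], c) for n, c in r.carbon_out.items()]
        in_carbons = [(self.l_index[n], c * self.carbons[n]) for n, c in r.carbon_in.items()]
        out_carbons = [(self.l_index[n], c * self.carbons[n]) for n, c in r.carbon_out.items()]
        denom_fwd = sum(c * self.carbons[n] for n, c in r.carbon_out.items()) + r.extra_out_carbons
        denom_bwd = sum(c * self.carbons[n] for n, c in r.carbon_in.items())
        return cin, cout, in_carbons, out_carbons, denom_fwd, denom_bwd

    def moiety_vector(self, members: dict[str, float]) -> np.ndarray:
        vec = np.zeros(len(self.species))
        for name, w in members.items():
            vec[self.s_index[name]] = w
        return vec


def yeast_network() -> Network:
    """The shipped carbon-storage network."""
    return Network(SPECIES, REACTIONS, volume_state=True)


#: Moiety memberships conserved by the stoichiometry.
ADENYLATE_MOIETY = {"ATP": 1.0, "ADP": 1.0, "AMP": 1.0}
NICOTINAMIDE_MOIETY = {"NAD": 1.0, "NADH": 1.0}
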