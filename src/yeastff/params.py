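"""Kinetic parameter sets: schema, validation and (de)serialization.

A :class:`ParameterSet` is a flat mapping of ``"REACTION.constant"`` keys to
floats (units: mM for Michaelis/inhibition constants, mM s^-1 for Vmax,
dimensionless for Hill coefficients, equilibrium constants and factors).
Every reaction of the shipped network declares the constants its rate law
needs; loading a file with unknown or missing keys fails with the offending
key named.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ParameterSet",
    "REQUIRED_KEYS",
    "ESTIMABLE_KEYS",
    "TREHALOSE_CYCLE_REACTIONS",
    "read_parameterset",
    "write_parameterset",
    "load_reference_parameters",
    "load_calibrated_parameters",
    "load_table1",
]

#: Constants each reaction's rate law resolves.  The network in
#: :mod:`yeastff.network` is validated against this registry.
REQUIRED_KEYS: dict[str, tuple[str, ...]] = {
    "HXT": ("Vmax", "Km", "Ki", "Keq", "GLCec_min"),
    "GLK": ("Vmax", "Km_GLC", "Km_ATP", "Ki_T6P"),
    "PGI": ("Vmax", "Km_G6P", "Km_F6P", "Keq"),
    "PFK": ("Vmax", "Km_F6P", "Km_ATP", "n", "L0", "Ki_ATP", "Ka_AMP"),
    "FBA": ("Vmax", "Km_FBP", "Km_DHAP", "Km_GAP", "Keq"),
    "TPI": ("Vmax", "Km_DHAP", "Km_GAP", "Keq"),
    "GAPDH": ("Vmax", "Km_GAP", "Km_NAD", "Km_BPG", "Km_NADH", "Km_PI", "Keq"),
    "PGK": ("Vmax", "Km_BPG", "Km_ADP", "Km_P3G", "Km_ATP", "Keq"),
    "GPM": ("Vmax", "Km_P3G", "Km_P2G", "Keq"),
    "ENO": ("Vmax", "Km_P2G", "Km_PEP", "Keq"),
    "PYK": ("Vmax", "K05_PEP", "n", "Ka_FBP", "Km_ADP"),
    "PDC": ("Vmax", "K05_PYR", "n"),
    "ADH": ("Vmax", "Km_ACE", "Km_NADH"),
    "G3PDH": ("Vmax", "Km_DHAP", "Km_NADH"),
    "GPP": ("Vmax", "Km_G3P"),
    "PGM1": ("Vmax", "Km_G1P", "Km_G6P", "Keq"),
    "UGP": ("Vmax", "Km_G1P", "Km_ATP", "Km_UDPG", "Ki_G1P", "Keq"),
    "TPS1": ("Vmax", "Km_G6P", "Km_UDPG"),
    "TPS2": ("Vmax", "Km_T6P"),
    "NTH1": ("Vmax", "Km_TRE"),
    "AGT1": ("Vmax", "Km_TREc", "Km_TREec", "Keq", "Ki_T6P"),
    "VACT": ("Vmax", "Km_TREc", "Km_TREv", "Keq"),
    "ATH1": ("Vmax", "Km_TREv", "Ki_T6P"),
    "GLYS": ("Ksat_UDPG", "v_chemostat"),
    "GLYD": ("Ksat_GLY", "v_chemostat"),
    "ATPASE": ("k",),
    "ADK": ("k", "Keq"),
    "MITONADH": ("Vmax", "Km_NADH"),
    "SINKG6P": ("Vmax", "Km"),
    "SINKP3G": ("Vmax", "Km"),
    "SINKPYR": ("Vmax", "Km", "factor"),
    "SINKACE": ("Vmax", "Km"),
    "PIBUF": ("k", "PI_ref"),
}

#: Constants that may be freed during estimation, per reaction.
ESTIMABLE_KEYS: dict[str, tuple[str, ...]] = {
    "HXT": ("Vmax", "Km"),
    "GLK": ("Vmax", "Km_GLC", "Ki_T6P"),
    "TPS1": ("Vmax",),
    "TPS2": ("Vmax",),
    "NTH1": ("Vmax", "Km_TRE"),
    "AGT1": ("Vmax",),
    "VACT": ("Vmax",),
    "ATH1": ("Vmax",),
    "ATPASE": ("k",),
}

#: Reactions that constitute the trehalose cycle; every screened enzyme
#: combination must contain them.
TREHALOSE_CYCLE_REACTIONS = ("TPS1", "TPS2", "NTH1", "AGT1", "VACT", "ATH1")

# Amplitude-class constants (maximal rates, rate constants, thresholds) may
# be zero — knocking an activity out is a legitimate configuration; shape
# constants (Km, Ki, Keq, Hill n, factors) must stay strictly positive.
_AMPLITUDE_SUFFIXES = ("Vmax", "k", "v_chemostat", "GLCec_min", "PI_ref")


def _is_amplitude(key: str) -> bool:
    return key.rsplit(".", 1)[1] in _AMPLITUDE_SUFFIXES


class ParameterError(ValueError):
    """Raised on schema violations in a parameter file."""


def _full_schema() -> frozenset[str]:
    return frozenset(
        f"{rxn}.{name}" for rxn, names in REQUIRED_KEYS.items() for name in names
    )


_SCHEMA = _full_schema()


@dataclass
class ParameterSet(Mapping):
    """Flat, validated mapping of kinetic constants.

    Parameters
    ----------
    values:
        Mapping of ``"REACTION.constant"`` to floats.
    role:
        Provenance of the set: ``"reference"`` (regularization anchor) or
        ``"estimated"``.
    """

    values: dict[str, float] = field(default_factory=dict)
    role: str = "reference"

    def __post_init__(self) -> None:
        self.validate()

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    # ------------------------------------------------------------------
    def get(self, reaction: str, name: str | None = None, default=None):
        if name is None:
            return self.values.get(reaction, default)
        return self.values.get(f"{reaction}.{name}", default)

    def validate(self) -> None:
        if self.role not in ("reference", "estimated"):
            raise ParameterError(f"unknown role {self.role!r}")
        for key, value in self.values.items():
            if key not in _SCHEMA:
                raise ParameterError(f"unknown parameter key {key!r}")
            value = float(value)
            if _is_amplitude(key):
                if value < 0:
                    raise ParameterError(f"{key} must be >= 0, got {value}")
            elif not value > 0:
                raise ParameterError(f"{key} must be > 0, got {value}")
            self.values[key] = value
        missing = _SCHEMA - set(self.values)
        if missing:
            raise ParameterError(f"missing parameter key {sorted(missing)[0]!r}")

    def replace(self, updates: Mapping[str, float], role: str | None = None) -> "ParameterSet":
        """Return a copy with ``updates`` applied."""
        vals = dict(self.values)
        vals.update({k: float(v) for k, v in updates.items()})
        return ParameterSet(vals, role or self.role)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), self.role)

    def free_keys_for(self, reactions: Iterable[str]) -> list[str]:
        """Estimable ``"RXN.const"`` keys for a reaction subset, in a
        deterministic order."""
        keys: list[str] = []
        for rxn in reactions:
            for name in ESTIMABLE_KEYS.get(rxn, ()):
                keys.append(f"{rxn}.{name}")
        return keys


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def read_parameterset(path) -> ParameterSet:
    """Read a parameter set from a flat-key JSON file.

    The file layout is ``{"role": ..., "values": {"RXN.const": float}}``.
    Unknown or missing keys raise :class:`ParameterError` naming the key.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "values" not in payload:
        raise ParameterError(f"{path}: expected an object with a 'values' field")
    return ParameterSet(dict(payload["values"]), payload.get("role", "reference"))


def write_parameterset(ps: ParameterSet, path) -> None:
    """Write a parameter set as sorted-key JSON (round-trip stable)."""
    payload = {
        "role": ps.role,
        "units": {"Vmax": "mM/s", "Km": "mM", "Ki": "mM", "Keq": "1"},
        "values": {k: ps.values[k] for k in sorted(ps.values)},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _data_path(name: str):
    return resources.files("yeastff.data").joinpath(name)


def load_reference_parameters() -> ParameterSet:
    """Shipped reference kinetic constants (pre-adaptation role)."""
    return read_parameterset(_data_path("params_reference.json"))


def load_calibrated_parameters() -> ParameterSet:
    """Shipped calibrated constants for the feast/famine regime (estimated
    transporter/phosphorylation values substituted into the reference set)."""
    return read_parameterset(_data_path("params_calibrated.json"))


def load_table1() -> dict[str, dict[str, float]]:
    """Reference/estimated value pairs for the adapted transport and
    phosphorylation constants, as shipped fixture data."""
    with open(_data_path("table1.json")) as fh:
        return json.load(fh)
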