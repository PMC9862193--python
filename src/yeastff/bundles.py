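"""Observation bundles: timestamped concentration/flux/enrichment tables.

The on-disk format is a single tidy CSV with columns
``table,series,time_s,value,sd,unit`` where ``table`` is one of ``conc``
(species concentrations, mM), ``flux`` (reaction rates, mM/s) or ``enrich``
(enrichment percentages).  Rows are canonically sorted on read, so files
with shuffled rows parse to the same bundle.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ObservationBundle", "read_bundle", "write_bundle"]

_TABLES = ("conc", "flux", "enrich")
_UNITS = {"conc": "mM", "flux": "mM/s", "enrich": "percent"}
_COLUMNS = ["table", "series", "time_s", "value", "sd", "unit"]


class BundleError(ValueError):
    """Schema violation in an observation bundle."""


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({"series": pd.Series(dtype=str),
                         "time_s": pd.Series(dtype=float),
                         "value": pd.Series(dtype=float),
                         "sd": pd.Series(dtype=float)})


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["series", "time_s"], kind="mergesort").reset_index(drop=True)


@dataclass
class ObservationBundle:
    """Concentration, flux and enrichment observations over a cycle.

    Each member table has columns ``series`` (species or reaction id),
    ``time_s``, ``value`` and ``sd``.  ``provenance`` records whether the
    bundle is experimental or synthetic.
    """

    conc: pd.DataFrame = field(default_factory=_empty_table)
    flux: pd.DataFrame = field(default_factory=_empty_table)
    enrich: pd.DataFrame = field(default_factory=_empty_table)
    provenance: str = "synthetic"
    cycle_s: float = 400.0

    def __post_init__(self):
        for name in _TABLES:
            df = getattr(self, name)
            missing = {"series", "time_s", "value", "sd"} - set(df.columns)
            if missing:
                raise BundleError(f"{name} table lacks columns {sorted(missing)}")
            df = _canonical(df[["series", "time_s", "value", "sd"]].copy())
            if len(df):
                if (df["sd"] <= 0).any():
                    raise BundleError(f"{name} table has non-positive sd")
                if ((df["time_s"] < 0) | (df["time_s"] > self.cycle_s)).any():
                    raise BundleError(f"{name} table has times outside [0, {self.cycle_s}]")
            setattr(self, name, df)
        if self.provenance not in ("experimental", "synthetic"):
            raise BundleError(f"unknown provenance {self.provenance!r}")

    def table(self, name: str) -> pd.DataFrame:
        if name not in _TABLES:
            raise BundleError(f"unknown table {name!r}")
        return getattr(self, name)

    def series_keys(self) -> list[tuple[str, str]]:
        """All (table, series) pairs present, in canonical order."""
        out = []
        for name in _TABLES:
            for s in sorted(self.table(name)["series"].unique()):
                out.append((name, s))
        return out

    def series(self, table: str, key: str) -> pd.DataFrame:
        df = self.table(table)
        return df[df["series"] == key]

    def equals(self, other: "ObservationBundle") -> bool:
        return all(self.table(n).equals(other.table(n)) for n in _TABLES)


def write_bundle(bundle: ObservationBundle, path) -> None:
    """Write a bundle as tidy CSV at fixed float precision (round-trip and
    bit-reproducible)."""
    frames = []
    for name in _TABLES:
        df = bundle.table(name).copy()
        df.insert(0, "table", name)
        df["unit"] = _UNITS[name]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)[_COLUMNS]
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format="%.12g")
    with open(path, "w") as fh:
        fh.write(f"# provenance={bundle.provenance} cycle_s={bundle.cycle_s:g}\n")
        fh.write(buf.getvalue())


def read_bundle(path) -> ObservationBundle:
    """Read a tidy-CSV bundle; a missing ``sd`` column gets a 5% default
    (with a warning); malformed rows raise with the row number."""
    import warnings

    with open(path) as fh:
        header = fh.readline()
        meta = {}
        if header.startswith("#"):
            for tok in header[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            body = fh.read()
        else:
            body = header + fh.read()
    df = pd.read_csv(io.StringIO(body))
    if "sd" not in df.columns:
        warnings.warn("bundle file lacks an sd column; applying 5% of |value|")
        df["sd"] = 0.05 * df["value"].abs().clip(lower=1e-9)
    required = {"table", "series", "time_s", "value", "sd"}
    if not required <= set(df.columns):
        raise BundleError(f"missing columns {sorted(required - set(df.columns))}")
    for col in ("time_s", "value", "sd"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna() & df[col].notna())
        if bad.size:
            raise BundleError(f"malformed {col!r} in data row {bad[0] + 1}")
        df[col] = converted
    tables = {}
    for name in _TABLES:
        tables[name] = df[df["table"] == name][["series", "time_s", "value", "sd"]]
    unknown = set(df["table"].unique()) - set(_TABLES)
    if unknown:
        raise BundleError(f"unknown table id {sorted(unknown)[0]!r}")
    return ObservationBundle(
        conc=tables["conc"], flux=tables["flux"], enrich=tables["enrich"],
        provenance=meta.get("provenance", "synthetic"),
        cycle_s=float(meta.get("cycle_s", 400.0)))
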