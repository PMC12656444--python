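"""Trait registry and tidy trait tables for the urban-tree stress pipeline.

The analysis operates on a fixed vocabulary of 17 leaf functional traits
spanning three classes:

* **structural** — SPAD (relative chlorophyll content), LT (leaf thickness),
  LTD (leaf temperature differential, leaf minus ambient);
* **fluorescence** — MultispeQ-style photosystem II parameters
  (PhiII, PhiNO, PhiNPQ, Fv'/Fm', gH+, vH+, LEF, qL);
* **biochemical** — oxidative-stress markers and antioxidants
  (TBARS, Proline, GSH, total proteins, APX, CAT).

Eight traits are *stress-indicative*: a larger raw value signals a worse
physiological state (TBARS, Proline, PhiNO, PhiNPQ, LTD, GSH, APX, CAT).
Downstream index construction inverts their normalized scores so that
"higher = healthier" holds uniformly.

Measurements live in a long (tidy) table with one row per
(species, condition, timepoint, replicate, trait) observation. Long format
is canonical because replicate counts differ by trait class (typically 12
fluorescence readings vs. triplicate biochemistry per group).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitDefinition",
    "TraitTableError",
    "CONDITIONS",
    "TIMEPOINTS",
    "STRESS_INDICATIVE",
    "default_registry",
    "load_registry",
    "resolve_trait",
    "TraitTable",
    "load_trait_table",
    "write_trait_table",
]

CONDITIONS = ("control", "urban")
TIMEPOINTS = ("June", "August")

#: Traits whose larger raw values indicate greater stress; their normalized
#: scores are inverted (1 - z) before entering the composite index.
STRESS_INDICATIVE = frozenset(
    {"TBARS", "Proline", "PhiNO", "PhiNPQ", "LTD", "GSH", "APX", "CAT"}
)


class TraitTableError(ValueError):
    """Raised for malformed or inconsistent trait tables."""


@dataclass(frozen=True)
class TraitDefinition:
    """A named trait with units, class, and stress direction.

    ``stress_indicative=True`` means larger raw values indicate worse
    condition; the normalized score is inverted downstream.
    """

    name: str
    units: str
    trait_class: str  # structural | fluorescence | biochemical
    stress_indicative: bool

    def __post_init__(self) -> None:
        if self.trait_class not in ("structural", "fluorescence", "biochemical"):
            raise ValueError(f"unknown trait class {self.trait_class!r}")


_DEFAULT_TRAITS = [
    # structural / water status
    ("SPAD", "index", "structural"),
    ("LT", "mm", "structural"),
    ("LTD", "degC", "structural"),
    # chlorophyll fluorescence / photosynthesis
    ("PhiII", "dimensionless", "fluorescence"),
    ("PhiNO", "dimensionless", "fluorescence"),
    ("PhiNPQ", "dimensionless", "fluorescence"),
    ("FvpFmp", "dimensionless", "fluorescence"),
    ("gH+", "dimensionless", "fluorescence"),
    ("vH+", "dimensionless", "fluorescence"),
    ("LEF", "umol electrons m^-2 s^-1", "fluorescence"),
    ("qL", "dimensionless", "fluorescence"),
    # biochemical
    ("TBARS", "nmol mg^-1 protein", "biochemical"),
    ("Proline", "nmol g^-1 FW", "biochemical"),
    ("GSH", "umol mg^-1 protein", "biochemical"),
    ("TotalProteins", "mg g^-1 FW", "biochemical"),
    ("APX", "U mg^-1 protein", "biochemical"),
    ("CAT", "U mg^-1 protein", "biochemical"),
]


def default_registry() -> dict[str, TraitDefinition]:
    """The 17-trait default registry with field-standard direction flags."""
    reg: dict[str, TraitDefinition] = {}
    for name, units, cls in _DEFAULT_TRAITS:
        reg[name] = TraitDefinition(name, units, cls, name in STRESS_INDICATIVE)
    return reg


def load_registry(path: str | Path) -> dict[str, TraitDefinition]:
    """Load a registry override from a YAML file.

    Expected layout: a mapping trait name -> {units, trait_class,
    stress_indicative}.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise TraitTableError(f"registry file {path} must be a mapping")
    reg: dict[str, TraitDefinition] = {}
    for name, spec in raw.items():
        reg[str(name)] = TraitDefinition(
            name=str(name),
            units=str(spec.get("units", "")),
            trait_class=str(spec["trait_class"]),
            stress_indicative=bool(spec["stress_indicative"]),
        )
    return reg


# Device exports spell trait names inconsistently (Phi2, PhiNPQ, Fv'/Fm', ...).
# Names are matched case-insensitively after stripping separators and primes.
_SYNONYMS = {
    "phi2": "PhiII",
    "phiii": "PhiII",
    "phino": "PhiNO",
    "phinpq": "PhiNPQ",
    "fvfm": "FvpFmp",
    "fvpfmp": "FvpFmp",
    "gh+": "gH+",
    "vh+": "vH+",
    "lef": "LEF",
    "ql": "qL",
    "spad": "SPAD",
    "ltd": "LTD",
    "lt": "LT",
    "leafthickness": "LT",
    "tbars": "TBARS",
    "proline": "Proline",
    "gsh": "GSH",
    "glutathione": "GSH",
    "totalproteins": "TotalProteins",
    "proteins": "TotalProteins",
    "apx": "APX",
    "cat": "CAT",
}


def _normalize_name(name: str) -> str:
    s = str(name).strip().replace("Φ", "phi").replace("Ф", "phi")
    s = re.sub(r"[\s_'′/\-\.]", "", s)
    return s.lower()


def resolve_trait(name: str, registry: Mapping[str, TraitDefinition]) -> str:
    """Map a free-form trait label onto its canonical registry name.

    Raises :class:`TraitTableError` if the label is unknown.
    """
    if name in registry:
        return name
    key = _normalize_name(name)
    canonical = _SYNONYMS.get(key)
    if canonical is None:
        # fall back to case-insensitive match against registry names
        for reg_name in registry:
            if _normalize_name(reg_name) == key:
                canonical = reg_name
                break
    if canonical is None or canonical not in registry:
        raise TraitTableError(f"unknown trait name {name!r}")
    return canonical


REQUIRED_COLUMNS = ("species", "condition", "timepoint", "replicate", "trait", "value")

#: key columns identifying a single observation
KEY_COLUMNS = ("species", "condition", "timepoint", "replicate", "trait")


class TraitTable:
    """Replicate-level long-format trait observations over the factorial design.

    Wraps a :class:`pandas.DataFrame` with columns
    ``species, condition, timepoint, replicate, trait, value``. Conditions are
    ``control``/``urban`` and timepoints ``June``/``August``; species labels are
    free. Trait names are canonicalized against a registry, duplicate
    observation keys are rejected, and missing values (NaN) are allowed —
    downstream operations state their own missing-data rules.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        registry: Mapping[str, TraitDefinition] | None = None,
        validate: bool = True,
    ) -> None:
        self.registry = dict(registry) if registry is not None else default_registry()
        if validate:
            df = self._validated(df)
        self.df = df.reset_index(drop=True)

    def _validated(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TraitTableError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()

        df["species"] = df["species"].astype(str)
        df["condition"] = df["condition"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        if bad:
            raise TraitTableError(f"condition must be one of {CONDITIONS}; got {bad}")
        df["timepoint"] = df["timepoint"].astype(str).str.strip().str.capitalize()
        bad = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
        if bad:
            raise TraitTableError(f"timepoint must be one of {TIMEPOINTS}; got {bad}")

        reps = pd.to_numeric(df["replicate"], errors="coerce")
        bad_rows = df.index[reps.isna() | (reps < 1) | (reps != reps.round())]
        if len(bad_rows):
            raise TraitTableError(
                f"replicate must be a positive integer; bad rows: {list(bad_rows[:10])}"
            )
        df["replicate"] = reps.astype(int)

        df["trait"] = [resolve_trait(t, self.registry) for t in df["trait"]]

        # float() round-trips shortest-repr decimals exactly (pd.to_numeric's
        # fast path can be off by one ulp, breaking write/load identity)
        def _parse(x):
            if x is None or (isinstance(x, float) and np.isnan(x)):
                return np.nan
            if isinstance(x, (int, float, np.floating, np.integer)):
                return float(x)
            s = str(x).strip()
            if s == "" or s.lower() in ("nan", "na"):
                return np.nan
            try:
                return float(s)
            except ValueError:
                return _parse  # sentinel: unparseable

        parsed = [_parse(x) for x in df["value"]]
        unparseable = [i for i, v in zip(df.index, parsed) if v is _parse]
        if unparseable:
            raise TraitTableError(
                "unparseable value(s) at row(s) "
                + ", ".join(str(i) for i in unparseable[:10])
            )
        df["value"] = np.asarray(parsed, dtype=float)

        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].drop_duplicates()
            raise TraitTableError(
                f"duplicate observation key(s): {keys.to_records(index=False)[:5]}"
            )
        return df

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        cols = list(REQUIRED_COLUMNS)
        a = self.df[cols].sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.df[cols].sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        return a.equals(b)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def to_wide(self) -> pd.DataFrame:
        """Pivot to samples x traits, indexed by the factorial key."""
        return self.df.pivot_table(
            index=["species", "condition", "timepoint", "replicate"],
            columns="trait",
            values="value",
            aggfunc="first",
        )

    def subset(self, **levels: str) -> "TraitTable":
        """Filter by factor levels and/or trait, e.g. ``subset(species="Tilia")``."""
        df = self.df
        for col, val in levels.items():
            if col not in ("species", "condition", "timepoint", "trait"):
                raise TraitTableError(f"cannot subset on {col!r}")
            df = df[df[col] == val]
        return TraitTable(df.copy(), registry=self.registry, validate=False)

    def group_means(self) -> pd.DataFrame:
        """Mean value per (species, condition, timepoint, trait) group."""
        return (
            self.df.groupby(["species", "condition", "timepoint", "trait"])["value"]
            .mean()
            .reset_index()
        )

    def is_balanced(self, trait: str) -> bool:
        """True when every condition x timepoint cell has the same replicate
        count >= 2 for this trait (per species)."""
        sub = self.df[self.df["trait"] == trait].dropna(subset=["value"])
        if sub.empty:
            return False
        for _, sp in sub.groupby("species"):
            counts = sp.groupby(["condition", "timepoint"]).size()
            if len(counts) != 4 or counts.nunique() != 1 or counts.min() < 2:
                return False
        return True

    def add_records(self, records: pd.DataFrame) -> "TraitTable":
        """Return a new table with extra rows appended (re-validated)."""
        df = pd.concat([self.df, records], ignore_index=True)
        return TraitTable(df, registry=self.registry)


def load_trait_table(
    path: str | Path,
    registry: Mapping[str, TraitDefinition] | None = None,
) -> TraitTable:
    """Read a comma- or tab-delimited tidy trait table.

    Header must contain ``species, condition, timepoint, replicate, trait,
    value``; the delimiter is sniffed. Comment lines starting with ``#`` are
    ignored (pipeline outputs carry metadata in such headers).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    return TraitTable(df, registry=registry)


def write_trait_table(
    table: TraitTable, path: str | Path, sep: str = ",", metadata: Iterable[str] = ()
) -> None:
    """Write a table as delimited text; ``load_trait_table`` round-trips it."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        table.df.to_csv(fh, sep=sep, index=False)
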