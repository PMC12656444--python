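"""Derived photosynthetic traits and effect-size descriptors.

Linear electron flow (LEF) through photosystem II is estimated from the PSII
quantum yield and incident light:

    LEF = PhiII * PAR * k,    k = 0.45

where PAR is photosynthetically active radiation (umol photons m^-2 s^-1) and
k approximately accounts for leaf absorptance and the fraction of absorbed
light reaching PSII. The leaf temperature differential (LTD) is leaf minus
ambient temperature — positive when the leaf is warmer than the air, i.e.
when transpirational cooling is impaired.

Percent and fold changes are the descriptors used when comparing urban vs.
control group means; both operate on group means, not replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .traits import TraitTable

__all__ = [
    "ABSORPTANCE_FACTOR",
    "LightContext",
    "ThermalContext",
    "compute_lef",
    "compute_ltd",
    "percent_change",
    "fold_change",
    "append_lef",
    "append_ltd",
]

#: Fraction of incident PAR driving PSII photochemistry (absorptance x
#: PSII partitioning); fixed by convention, overridable per call.
ABSORPTANCE_FACTOR = 0.45


@dataclass(frozen=True)
class LightContext:
    """PSII quantum yield and incident light for one measurement."""

    phi2: float  # quantum yield of PSII, in [0, 1]
    par: float  # umol photons m^-2 s^-1, >= 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi2) or not 0.0 <= self.phi2 <= 1.0:
            raise ValueError(f"phi2 must be in [0, 1]; got {self.phi2}")
        if not np.isfinite(self.par) or self.par < 0:
            raise ValueError(f"par must be >= 0; got {self.par}")


@dataclass(frozen=True)
class ThermalContext:
    """Paired leaf and ambient temperatures (degC)."""

    leaf_temp: float
    ambient_temp: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.leaf_temp) and np.isfinite(self.ambient_temp)):
            raise ValueError("temperatures must be finite")


def compute_lef(ctx: LightContext, factor: float = ABSORPTANCE_FACTOR) -> float:
    """Linear electron flow: phi2 * par * factor (umol electrons m^-2 s^-1)."""
    return ctx.phi2 * ctx.par * factor


def compute_ltd(ctx: ThermalContext) -> float:
    """Leaf temperature differential: leaf minus ambient (degC, signed)."""
    return ctx.leaf_temp - ctx.ambient_temp


def percent_change(reference: float, value: float) -> float:
    """100 * (value - reference) / reference; negative means a decrease."""
    if reference == 0 or not np.isfinite(reference):
        raise ValueError("reference must be nonzero and finite")
    return 100.0 * (value - reference) / reference


def fold_change(reference: float, value: float) -> float:
    """value / reference for a strictly positive reference."""
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError("reference must be > 0")
    if value < 0:
        raise ValueError("value must be >= 0")
    return value / reference


SampleKey = tuple[str, str, str, int]  # (species, condition, timepoint, replicate)


def _per_sample(values, keys, what: str) -> pd.Series:
    if np.isscalar(values):
        return pd.Series(float(values), index=keys)
    if isinstance(values, Mapping):
        values = pd.Series(values)
    if isinstance(values, pd.Series):
        missing = [k for k in keys if k not in values.index]
        if missing:
            raise ValueError(f"{what} missing for sample(s) {missing[:5]}")
        return values.loc[keys].astype(float)
    raise TypeError(f"{what} must be a scalar, mapping, or Series")


def append_lef(
    table: TraitTable,
    par,
    factor: float = ABSORPTANCE_FACTOR,
) -> TraitTable:
    """Append LEF rows computed from the table's PhiII observations.

    ``par`` is the incident PAR: a scalar (protocol constant) or a mapping /
    Series keyed by (species, condition, timepoint, replicate) for per-leaf
    ambient readings. Samples lacking PhiII are skipped. If the table already
    contains LEF rows a ValueError is raised.
    """
    if "LEF" in table.df["trait"].values:
        raise ValueError("table already contains LEF rows")
    phi2 = table.df[table.df["trait"] == "PhiII"].dropna(subset=["value"])
    if phi2.empty:
        raise ValueError("no PhiII observations to derive LEF from")
    keys = list(
        phi2[["species", "condition", "timepoint", "replicate"]].itertuples(
            index=False, name=None
        )
    )
    par_per = _per_sample(par, keys, "PAR")
    lef = [
        compute_lef(LightContext(p, q), factor)
        for p, q in zip(phi2["value"].to_numpy(), par_per.to_numpy())
    ]
    rows = phi2.copy()
    rows["trait"] = "LEF"
    rows["value"] = lef
    return table.add_records(rows)


def append_ltd(table: TraitTable, leaf_temp, ambient_temp) -> TraitTable:
    """Append LTD rows (leaf minus ambient, degC).

    ``leaf_temp`` and ``ambient_temp`` are scalars or mappings / Series keyed
    by (species, condition, timepoint, replicate); LTD is added for every key
    present in ``leaf_temp`` (all samples if scalar).
    """
    if "LTD" in table.df["trait"].values:
        raise ValueError("table already contains LTD rows")
    samples = table.df[
        ["species", "condition", "timepoint", "replicate"]
    ].drop_duplicates()
    keys = list(samples.itertuples(index=False, name=None))
    if not np.isscalar(leaf_temp):
        lt = pd.Series(leaf_temp) if isinstance(leaf_temp, Mapping) else leaf_temp
        keys = [k for k in keys if k in lt.index]
        samples = pd.DataFrame(keys, columns=samples.columns)
    leaf = _per_sample(leaf_temp, keys, "leaf_temp")
    amb = _per_sample(ambient_temp, keys, "ambient_temp")
    ltd = [
        compute_ltd(ThermalContext(a, b))
        for a, b in zip(leaf.to_numpy(), amb.to_numpy())
    ]
    rows = samples.copy()
    rows["trait"] = "LTD"
    rows["value"] = ltd
    return table.add_records(rows)
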