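"""Composite tree-health index: normalization, inversion, THRI, contributions.

The pipeline's core statistic is an unweighted composite of min–max
normalized trait scores. Each trait j is rescaled over its normalization
scope to

    z_ij = (x_ij - min_j) / (max_j - min_j)  in [0, 1],

stress-indicative traits are direction-harmonized by z -> 1 - z so that
higher always means healthier, and the Tree Health Risk Index of sample i is
the mean of its available trait scores:

    THRI_i = (1/n) * sum_j z_ij.

Trait contributions are the column means of the harmonized matrix — the mean
normalized value of each trait across all samples — which rank the traits by
their weight in the composite.

Normalization scope is consequential and explicit: ``within-species``
(default; each species' own trait ranges, matching per-species index
reporting) or ``global`` (one pooled range per trait across species, matching
cross-species heatmap construction). The scope travels with the matrix and
into every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .traits import STRESS_INDICATIVE, TraitDefinition, TraitTable

__all__ = [
    "NormalizedMatrix",
    "ThriResult",
    "minmax_normalize",
    "invert_stress_traits",
    "compute_thri",
    "trait_contributions",
    "aggregate_pseudo_replicates",
]

SCOPES = ("within-species", "global")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Samples x traits matrix of min–max scores in [0, 1].

    ``data`` is indexed by (species, condition, timepoint, replicate).
    ``inverted`` records which stress-indicative traits have already been
    direction-harmonized; ``constant_traits`` records traits that were
    constant within at least one scope unit (their scores there are 0.5).
    """

    data: pd.DataFrame
    scope: str
    inverted: frozenset = field(default_factory=frozenset)
    constant_traits: frozenset = field(default_factory=frozenset)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def check(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("normalized entries must lie in [0, 1]")


@dataclass(frozen=True)
class ThriResult:
    """Per-sample composite indices plus group summaries and contributions."""

    per_sample: pd.Series  # index: (species, condition, timepoint, replicate)
    group_summary: pd.DataFrame  # index: (species, condition, timepoint); mean/se/n
    contributions: pd.Series  # trait -> mean normalized value, descending
    coverage: pd.Series  # per-sample count of traits entering the mean
    scope: str


def minmax_normalize(table: TraitTable, scope: str = "within-species") -> NormalizedMatrix:
    """Min–max scale every trait to [0, 1] over the given scope.

    Within each scope unit (one species, or the pooled data for ``global``)
    each trait is mapped by (x - min) / (max - min). Traits constant within a
    scope unit map to 0.5 there and are flagged; traits entirely missing in a
    unit stay missing (warned). Missing observations remain NaN.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}; got {scope!r}")
    wide = table.to_wide()
    if wide.empty:
        raise ValueError("cannot normalize an empty table")

    out = wide.astype(float).copy()
    constant: set[str] = set()
    units = (
        [(sp, wide.xs(sp, level="species", drop_level=False)) for sp in
         wide.index.get_level_values("species").unique()]
        if scope == "within-species"
        else [("all", wide)]
    )
    for unit_name, block in units:
        for trait in block.columns:
            col = block[trait]
            n_obs = col.notna().sum()
            if n_obs == 0:
                warnings.warn(
                    f"trait {trait!r} has no observations in scope unit "
                    f"{unit_name!r}; left missing"
                )
                continue
            lo, hi = col.min(), col.max()
            if hi - lo == 0:
                out.loc[block.index, trait] = np.where(col.notna(), 0.5, np.nan)
                constant.add(trait)
            else:
                out.loc[block.index, trait] = (col - lo) / (hi - lo)
    if out.notna().any().any() and set(out.columns) == constant:
        warnings.warn("all traits constant in scope; matrix is uniformly 0.5")
    m = NormalizedMatrix(
        data=out, scope=scope, inverted=frozenset(), constant_traits=frozenset(constant)
    )
    m.check()
    return m


def invert_stress_traits(
    m: NormalizedMatrix,
    registry: Mapping[str, TraitDefinition] | None = None,
) -> NormalizedMatrix:
    """Direction-harmonize: stress-indicative trait scores become 1 - z.

    Applying this twice is an error (the operation is a guarded involution),
    and the returned matrix records the inverted trait set.
    """
    stress = (
        {n for n, d in registry.items() if d.stress_indicative}
        if registry is not None
        else set(STRESS_INDICATIVE)
    )
    to_invert = sorted(stress & set(m.data.columns))
    already = set(m.inverted) & set(to_invert)
    if already:
        raise ValueError(f"traits already inverted: {sorted(already)}")
    data = m.data.copy()
    for trait in to_invert:
        data[trait] = 1.0 - data[trait]
    return replace(m, data=data, inverted=m.inverted | frozenset(to_invert))


def _require_harmonized(m: NormalizedMatrix) -> None:
    pending = (STRESS_INDICATIVE & set(m.data.columns)) - set(m.inverted)
    if pending:
        raise ValueError(
            f"matrix not direction-harmonized; stress traits pending inversion: "
            f"{sorted(pending)}"
        )


def compute_thri(m: NormalizedMatrix) -> ThriResult:
    """Per-sample THRI plus group mean ± SE and trait contributions.

    THRI of a sample is the mean over its *available* trait scores (missing
    entries shrink the denominator; the per-sample coverage is reported).
    Samples with zero available traits are excluded with a warning. SE uses
    the (n-1) sample standard deviation over replicate THRIs.
    """
    _require_harmonized(m)
    coverage = m.data.notna().sum(axis=1)
    empty = coverage[coverage == 0]
    if len(empty):
        warnings.warn(f"{len(empty)} sample(s) with no trait scores excluded")
    data = m.data.loc[coverage > 0]
    per_sample = data.mean(axis=1, skipna=True)

    grouped = per_sample.groupby(level=["species", "condition", "timepoint"])
    summary = grouped.agg(mean="mean", n="size")
    sd = grouped.std(ddof=1)
    summary["se"] = sd / np.sqrt(summary["n"])
    summary = summary[["mean", "se", "n"]]

    contributions = data.mean(axis=0, skipna=True).sort_values(ascending=False)
    return ThriResult(
        per_sample=per_sample,
        group_summary=summary,
        contributions=contributions,
        coverage=coverage[coverage > 0],
        scope=m.scope,
    )


def trait_contributions(m: NormalizedMatrix) -> tuple[pd.Series, list[str]]:
    """Mean normalized value per trait across samples, with descending ranking."""
    _require_harmonized(m)
    contrib = m.data.mean(axis=0, skipna=True).sort_values(ascending=False)
    return contrib, list(contrib.index)


def aggregate_pseudo_replicates(table: TraitTable, k: int = 3) -> TraitTable:
    """Collapse each group's replicates into ``k`` balanced pseudo-replicates.

    Replicate ids are sorted and dealt round-robin into k bins per
    (species, condition, timepoint); each bin's trait values are averaged.
    Used to mirror group-level index reporting (e.g. n = 3 per group) when
    raw replicate counts are larger. Deterministic by construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.df.copy()
    reps = df[["species", "condition", "timepoint", "replicate"]].drop_duplicates()
    bin_map: dict[tuple, int] = {}
    for _, grp in reps.groupby(["species", "condition", "timepoint"]):
        ordered = sorted(grp["replicate"])
        if len(ordered) < k:
            raise ValueError(
                f"group has {len(ordered)} replicates; cannot form {k} pseudo-replicates"
            )
        for i, rep in enumerate(ordered):
            key = tuple(grp.iloc[0][["species", "condition", "timepoint"]]) + (rep,)
            bin_map[key] = i % k + 1
    df["replicate"] = [
        bin_map[(s, c, t, r)]
        for s, c, t, r in df[
            ["species", "condition", "timepoint", "replicate"]
        ].itertuples(index=False, name=None)
    ]
    agg = (
        df.groupby(["species", "condition", "timepoint", "replicate", "trait"])[
            "value"
        ]
        .mean()
        .reset_index()
    )
    return TraitTable(agg, registry=table.registry)
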