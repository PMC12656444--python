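"""Per-species factorial inference: 2x2 ANOVA, post hoc letters, assumptions.

Each trait is analyzed per species with a two-way fixed-effects ANOVA over
timepoint (T: June/August) and condition (C: control/urban), reporting the
T, C and TxC terms against the residual. Balanced designs use the closed-form
sums of squares from cell and marginal means; unbalanced data fall back to
Type-II sums of squares via model comparison (statsmodels OLS), which is
appropriate here because the interaction is tested last and there are no
covariates.

Post hoc pairwise comparisons across the four condition x timepoint cells use
Tukey's HSD (studentized-range adjusted p) by default, or Sidak-adjusted
pairwise t tests. Results are summarized as a compact letter display (CLD):
letters assigned by insert-and-absorb so that two cells share a letter iff
they are *not* significantly different; 'a' goes to the highest cell mean.

Assumption screening follows common practice: Shapiro–Wilk per group for
normality and Bartlett across groups for homogeneity of variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTerm",
    "AnovaResult",
    "PosthocResult",
    "AssumptionReport",
    "significance_codes",
    "two_way_anova",
    "two_way_anova_cells",
    "tukey_hsd",
    "compact_letter_display",
    "assumption_checks",
    "anova_by_species_trait",
]


def significance_codes(p: float) -> str:
    """Map a p value to the conventional code: *** / ** / * / ns."""
    if p is None or not np.isfinite(p):
        return "na"
    if not 0 <= p <= 1:  # p == 0 tolerated: sf() underflows for huge F
        raise ValueError(f"p must be in [0, 1]; got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class AnovaTerm:
    ss: float
    df: float
    ms: float
    F: float  # NaN for the residual row or degenerate fits
    p: float

    @property
    def code(self) -> str:
        return significance_codes(self.p)


@dataclass(frozen=True)
class AnovaResult:
    """Factorial decomposition with terms T, C, TxC and residual."""

    terms: dict[str, AnovaTerm]
    ss_total: float
    balanced: bool
    ss_type: str  # "balanced" (closed form) or "II" (model comparison)
    degenerate: bool = False  # zero residual variance: F/p undefined

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("T", "C", "TxC", "residual"):
            t = self.terms[name]
            rows.append(
                {
                    "term": name,
                    "SS": t.ss,
                    "df": t.df,
                    "MS": t.ms,
                    "F": t.F,
                    "p": t.p,
                    "code": t.code if name != "residual" else "",
                }
            )
        return pd.DataFrame(rows)


def two_way_anova_cells(y: np.ndarray) -> AnovaResult:
    """Closed-form balanced 2x2 ANOVA on an array of shape (2, 2, r).

    Axis 0 is factor T (timepoint), axis 1 factor C (condition), axis 2 the
    replicates. This is the fast path used by simulations; `two_way_anova`
    routes balanced tidy data through it.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3 or y.shape[:2] != (2, 2):
        raise ValueError("expected a (2, 2, r) array")
    r = y.shape[2]
    if r < 2:
        raise ValueError("each cell needs >= 2 replicates")
    n = 4 * r
    grand = y.mean()
    mean_t = y.mean(axis=(1, 2))
    mean_c = y.mean(axis=(0, 2))
    mean_cell = y.mean(axis=2)

    ss_t = 2 * r * float(np.sum((mean_t - grand) ** 2))
    ss_c = 2 * r * float(np.sum((mean_c - grand) ** 2))
    ss_cells = r * float(np.sum((mean_cell - grand) ** 2))
    ss_txc = ss_cells - ss_t - ss_c
    ss_total = float(np.sum((y - grand) ** 2))
    ss_res = ss_total - ss_cells
    df_res = n - 4

    def term(ss: float, df: float, ms_res: float) -> AnovaTerm:
        ms = ss / df
        if ms_res > 0:
            F = ms / ms_res
            p = float(sps.f.sf(F, df, df_res))
        else:
            F, p = math.nan, math.nan
        return AnovaTerm(ss=ss, df=df, ms=ms, F=F, p=p)

    ms_res = ss_res / df_res
    terms = {
        "T": term(ss_t, 1, ms_res),
        "C": term(ss_c, 1, ms_res),
        "TxC": term(ss_txc, 1, ms_res),
        "residual": AnovaTerm(ss=ss_res, df=df_res, ms=ms_res, F=math.nan, p=math.nan),
    }
    return AnovaResult(
        terms=terms,
        ss_total=ss_total,
        balanced=True,
        ss_type="balanced",
        degenerate=ms_res <= 0,
    )


def _anova_type2(df: pd.DataFrame) -> AnovaResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(timepoint) * C(condition)", data=df).fit()
    tbl = sm.stats.anova_lm(model, typ=2)
    name_map = {
        "C(timepoint)": "T",
        "C(condition)": "C",
        "C(timepoint):C(condition)": "TxC",
        "Residual": "residual",
    }
    terms: dict[str, AnovaTerm] = {}
    for raw, name in name_map.items():
        row = tbl.loc[raw]
        ss, dof = float(row["sum_sq"]), float(row["df"])
        terms[name] = AnovaTerm(
            ss=ss,
            df=dof,
            ms=ss / dof,
            F=float(row.get("F", math.nan)) if name != "residual" else math.nan,
            p=float(row.get("PR(>F)", math.nan)) if name != "residual" else math.nan,
        )
    ss_total = float(((df["value"] - df["value"].mean()) ** 2).sum())
    return AnovaResult(
        terms=terms,
        ss_total=ss_total,
        balanced=False,
        ss_type="II",
        degenerate=terms["residual"].ms <= 0,
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    timepoint: str = "timepoint",
    condition: str = "condition",
) -> AnovaResult:
    """Two-way ANOVA of one trait over the 2x2 timepoint x condition design.

    ``data`` holds one row per replicate. Both factors must have exactly two
    observed levels and every cell >= 2 replicates. Balanced cells take the
    closed-form path; unbalanced cells use Type-II sums of squares.
    """
    df = data[[timepoint, condition, value]].dropna()
    df = df.rename(columns={timepoint: "timepoint", condition: "condition", value: "value"})
    t_levels = sorted(df["timepoint"].unique())
    c_levels = sorted(df["condition"].unique())
    if len(t_levels) != 2 or len(c_levels) != 2:
        raise ValueError("both factors must have exactly 2 observed levels")
    counts = df.groupby(["timepoint", "condition"]).size()
    if len(counts) != 4:
        raise ValueError("empty design cell(s)")
    if counts.min() < 2:
        raise ValueError("every cell needs >= 2 replicates")
    if counts.nunique() == 1:
        r = int(counts.iloc[0])
        y = np.empty((2, 2, r))
        for i, t in enumerate(t_levels):
            for j, c in enumerate(c_levels):
                y[i, j] = df.loc[
                    (df["timepoint"] == t) & (df["condition"] == c), "value"
                ].to_numpy()
        return two_way_anova_cells(y)
    return _anova_type2(df)


@dataclass(frozen=True)
class PosthocResult:
    """All-pairs adjusted p values over design cells plus a letter display."""

    pairwise: dict[tuple[Hashable, Hashable], float]
    letters: dict[Hashable, str]
    method: str  # tukey | sidak
    alpha: float
    cells: tuple = field(default_factory=tuple)  # descending-mean order

    def p_value(self, a: Hashable, b: Hashable) -> float:
        return self.pairwise.get((a, b), self.pairwise.get((b, a), math.nan))


def tukey_hsd(
    cell_means: Mapping[Hashable, float],
    cell_ns: Mapping[Hashable, int],
    ms_residual: float,
    df_residual: float,
    alpha: float = 0.05,
    method: str = "tukey",
) -> PosthocResult:
    """Pairwise comparisons of cell means against a pooled residual.

    ``tukey``: p from the studentized range with k = number of cells, using
    the Tukey–Kramer standard error for (possibly) unequal cell sizes.
    ``sidak``: two-sided pooled-t p values with Sidak multiplicity adjustment.
    Letters come from :func:`compact_letter_display` at level ``alpha``,
    ordered so 'a' labels the highest mean.
    """
    cells = list(cell_means)
    if len(cells) < 2:
        raise ValueError("need >= 2 cells")
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    if ms_residual < 0:
        raise ValueError("ms_residual must be >= 0")
    k = len(cells)
    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple, float] = {}
    for a, b in itertools.combinations(cells, 2):
        diff = abs(cell_means[a] - cell_means[b])
        ninv = 1.0 / cell_ns[a] + 1.0 / cell_ns[b]
        if ms_residual == 0:
            p = 1.0 if diff == 0 else 0.0
        elif method == "tukey":
            se = math.sqrt(ms_residual / 2.0 * ninv)
            q = diff / se
            p = float(sps.studentized_range.sf(q, k, df_residual))
        elif method == "sidak":
            se = math.sqrt(ms_residual * ninv)
            t = diff / se
            p_raw = 2.0 * float(sps.t.sf(t, df_residual))
            p = 1.0 - (1.0 - min(p_raw, 1.0)) ** n_pairs
        else:
            raise ValueError(f"unknown post hoc method {method!r}")
        pairwise[(a, b)] = min(max(p, 0.0), 1.0)

    ordered = sorted(cells, key=lambda c: -cell_means[c])
    sig = {
        pair for pair, p in pairwise.items() if np.isfinite(p) and p < alpha
    }
    letters = compact_letter_display(sig, ordered)
    return PosthocResult(
        pairwise=pairwise,
        letters=letters,
        method=method,
        alpha=alpha,
        cells=tuple(ordered),
    )


def compact_letter_display(
    sig_pairs: set[tuple[Hashable, Hashable]],
    cells: Sequence[Hashable],
) -> dict[Hashable, str]:
    """Insert-and-absorb compact letter display.

    Given the symmetric, irreflexive relation of significantly different
    pairs, assign lowercase letters so that two cells share at least one
    letter iff their pair is NOT significant. ``cells`` fixes the letter
    order: the first cell (conventionally the highest mean) gets 'a'.
    """
    cells = list(cells)
    index = {c: i for i, c in enumerate(cells)}
    norm = set()
    for a, b in sig_pairs:
        if a == b:
            raise ValueError("significance relation must be irreflexive")
        if a not in index or b not in index:
            raise ValueError(f"pair ({a!r}, {b!r}) references unknown cell")
        norm.add((a, b) if index[a] < index[b] else (b, a))

    columns: list[set] = [set(cells)]
    for a, b in sorted(norm, key=lambda p: (index[p[0]], index[p[1]])):
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {a}, col - {b}):
                # absorb: keep only maximal columns
                if new and not any(new <= other for other in columns):
                    columns = [c for c in columns if not c <= new]
                    columns.append(new)

    columns.sort(key=lambda col: min(index[c] for c in col))
    if len(columns) > 26:
        raise ValueError("letter display would need more than 26 letters")
    letters: dict[Hashable, list[str]] = {c: [] for c in cells}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for c in col:
            letters[c].append(letter)
    return {c: "".join(ls) for c, ls in letters.items()}


@dataclass(frozen=True)
class AssumptionReport:
    """Shapiro–Wilk normality and Bartlett homogeneity screening at alpha."""

    shapiro_p: dict[Hashable, float | None]  # None: not computed (n < 3)
    bartlett_p: float | None
    alpha: float
    normality_ok: bool | None
    homogeneity_ok: bool | None


def assumption_checks(
    values: Sequence[float],
    groups: Sequence[Hashable],
    alpha: float = 0.05,
) -> AssumptionReport:
    """Per-group Shapiro–Wilk and across-group Bartlett tests.

    Groups with fewer than 3 observations get no normality p (flagged None);
    Bartlett requires >= 2 groups each with >= 2 observations. A check's
    overall flag is None when it could not be computed at all.
    """
    s = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    s = s.dropna(subset=["value"])
    shapiro_p: dict[Hashable, float | None] = {}
    for g, sub in s.groupby("group", sort=False):
        x = sub["value"].to_numpy()
        if len(x) >= 3 and np.ptp(x) > 0:
            shapiro_p[g] = float(sps.shapiro(x).pvalue)
        else:
            shapiro_p[g] = None
    computed = [p for p in shapiro_p.values() if p is not None]
    normality_ok = min(computed) >= alpha if computed else None

    arrays = [sub["value"].to_numpy() for _, sub in s.groupby("group", sort=False)]
    arrays = [a for a in arrays if len(a) >= 2]
    if len(arrays) >= 2 and all(np.ptp(a) > 0 for a in arrays):
        bartlett_p = float(sps.bartlett(*arrays).pvalue)
        homogeneity_ok = bartlett_p >= alpha
    else:
        bartlett_p, homogeneity_ok = None, None
    return AssumptionReport(
        shapiro_p=shapiro_p,
        bartlett_p=bartlett_p,
        alpha=alpha,
        normality_ok=normality_ok,
        homogeneity_ok=homogeneity_ok,
    )


def anova_by_species_trait(
    table,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the per-species, per-trait 2x2 ANOVA plus post hoc letters.

    Returns ``(anova_long, posthoc_long)``: the first has one row per
    species x trait x term with SS/df/F/p and significance code; the second
    one row per species x trait x cell with the cell mean, n and CLD letter.
    Species x trait combinations lacking a full 2x2 design (or with < 2
    replicates in a cell) are skipped.
    """
    anova_rows, posthoc_rows = [], []
    df = table.df.dropna(subset=["value"])
    for (species, trait), sub in df.groupby(["species", "trait"]):
        counts = sub.groupby(["timepoint", "condition"]).size()
        if len(counts) != 4 or counts.min() < 2:
            continue
        res = two_way_anova(sub)
        for term in ("T", "C", "TxC", "residual"):
            t = res.terms[term]
            anova_rows.append(
                {
                    "species": species,
                    "trait": trait,
                    "term": term,
                    "SS": t.ss,
                    "df": t.df,
                    "MS": t.ms,
                    "F": t.F,
                    "p": t.p,
                    "code": t.code if term != "residual" else "",
                }
            )
        if res.degenerate:
            continue
        cells = sub.groupby(["condition", "timepoint"])["value"]
        means = cells.mean().to_dict()
        ns = cells.size().to_dict()
        ph = tukey_hsd(
            means,
            ns,
            ms_residual=res.terms["residual"].ms,
            df_residual=res.terms["residual"].df,
            alpha=alpha,
            method=posthoc,
        )
        for cell in means:
            posthoc_rows.append(
                {
                    "species": species,
                    "trait": trait,
                    "condition": cell[0],
                    "timepoint": cell[1],
                    "mean": means[cell],
                    "n": ns[cell],
                    "letters": ph.letters[cell],
                    "method": posthoc,
                }
            )
    return pd.DataFrame(anova_rows), pd.DataFrame(posthoc_rows)
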