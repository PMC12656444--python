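# Methods

## Design and scope

The package analyzes leaf functional traits measured on a balanced factorial
design — species × condition (control vs. urban) × timepoint (June baseline
vs. August stress peak) × replicate — and integrates them into a composite
vitality score, the Tree Health Risk Index (THRI). The trait vocabulary is
fixed at 17 traits in three classes: structural (SPAD, leaf thickness LT,
leaf temperature differential LTD), chlorophyll fluorescence (ΦII, ΦNO,
ΦNPQ, Fv′/Fm′, gH⁺, vH⁺, LEF, qL), and biochemical (TBARS, proline, GSH,
total proteins, APX, CAT). Eight traits are stress-indicative — TBARS,
proline, ΦNO, ΦNPQ, LTD, GSH, APX, CAT — meaning larger raw values signal
worse physiological state; this set is pinned by a regression test and can
be overridden through a YAML registry.

Tables are long-format (one row per observation) because replicate counts
differ by trait class: fluorescence parameters are read 12 times per group,
biochemical assays in triplicate. Trait names are matched
case-insensitively with a synonym map (Phi2 → PhiII, Fv'/Fm' → FvpFmp, …)
because device exports vary. Missing values are allowed and handled
operation by operation.

## Derived traits

* **LEF** = ΦII × PAR × k with k = 0.45, the conventional factor for leaf
  absorptance times the fraction of absorbed quanta reaching PSII. k is a
  fixed constant, overridable per call; PAR may be a protocol constant or a
  per-leaf reading keyed by sample.
* **LTD** = leaf − ambient temperature (°C, signed). The sign convention is
  chosen so that impaired transpirational cooling (a warmer leaf) yields a
  larger LTD, which is why LTD is classed stress-indicative.
* Percent change 100·(x − ref)/ref and fold change x/ref are computed on
  group means, as effect descriptors, and reported to two decimals.

## Normalization scope and the composite index

Min–max scaling needs a pool over which min and max are taken, and the
choice is consequential. Two scopes are first-class and recorded in all
output metadata:

* **within-species** (default): each species' own trait ranges; matches
  per-species index reporting and per-species statistics. A species' score
  then measures where a sample sits within that species' observed range.
* **global**: pooled ranges across species; appropriate when species are
  compared on a common scale, e.g. for the cross-species clustered heatmap.

Traits constant within a scope unit map to 0.5 and are flagged rather than
dropped, keeping the index denominator interpretable; traits absent from a
unit are left missing with a warning. Per sample, THRI is the mean of the
*available* harmonized scores (the denominator shrinks with missingness and
per-sample coverage is reported). Group summaries use SE = sd/√n with the
(n − 1) standard deviation. Inversion of stress traits is a guarded
involution: applying it twice raises instead of silently round-tripping.

Because fluorescence and biochemistry have different replicate counts, a
raw replicate-level index mixes samples covering 13 traits with samples
covering only 8, implicitly down-weighting the biochemical block.
`aggregate_pseudo_replicates(table, k)` therefore deals each group's sorted
replicate ids round-robin into k balanced bins and averages within bins,
yielding k complete-coverage pseudo-replicates per group (k = 3 matches the
reported group size of the index and gives every trait class its intended
weight). Group means are preserved exactly when bins are balanced. Both
modes are exposed; the pipeline default is replicate-level, with
`pseudo_reps=3` used wherever the composite is meant to integrate all trait
classes evenly — including the species-ordering analysis below.

Invariants tested: THRI and contributions lie in [0, 1]; positive affine
transforms of any raw trait leave the normalized matrix, THRI and
contributions unchanged; raising a stress-indicative raw value of one
sample (extremes fixed) never raises its THRI; the mean of contributions
equals the mean per-sample THRI exactly on complete data; and the whole
chain matches a naive from-definition recomputation on small matrices.

## Factorial statistics

Per species and trait, a two-way fixed-effects ANOVA decomposes variance
into timepoint (T), condition (C), T×C and residual. Balanced 2×2 designs
use the closed-form sums of squares from cell and marginal means (partition
identity verified to 1e−9 relative); unbalanced data use Type-II sums of
squares via model comparison (statsmodels OLS) — defensible here because
there are no covariates and the interaction is tested last. Zero residual
variance is flagged degenerate with undefined F/p. Significance codes
follow the usual convention (ns, *, **, *** at 0.05/0.01/0.001).

Post hoc comparisons over the four condition × timepoint cells use Tukey's
HSD by default: p values from the studentized range distribution
(`scipy.stats.studentized_range`, accurate to well below 1e−4 in the tested
range) with the Tukey–Kramer standard error for unequal cell sizes;
Sidak-adjusted pooled-t comparisons are available by flag. Letters come
from the insert-and-absorb compact letter display: starting from one column
holding all cells, every significant pair splits each column containing
both, and non-maximal columns are absorbed. The algorithm guarantees the
contract "two cells share a letter iff not significantly different" for
arbitrary symmetric irreflexive relations, which a property test verifies
exhaustively over random relations; letters are ordered so 'a' labels the
highest cell mean. Assumption screening: Shapiro–Wilk per group (n ≥ 3) and
Bartlett across groups, with explicit not-computed flags below the minimum
group sizes. No transformation is applied automatically on failure, and no
multiplicity correction is applied across traits.

Calibration: under the null generator the condition-effect rejection rate
at α = 0.05 over 2000 simulations falls within [0.035, 0.065] (exact F-test
under Gaussian noise; the observed rate is ≈ 0.05).

## Clustering

Profiles are clustered agglomeratively with Euclidean distance and complete
linkage, on the group-mean harmonized matrix by default (treatment
combinations × traits; replicate-level clustering is available through the
same functions). Missing entries are handled pairwise-complete with the
squared distance rescaled by p/m (p coordinates total, m observed) to keep
distances comparable across pairs. The linkage is written here rather than
delegated because reproducibility requires a documented tie-break — equal
merge heights resolve toward the pair containing the lowest original leaf
index — which library implementations do not guarantee;
`scipy.cluster.hierarchy` serves as the independent oracle in tests, along
with an exhaustive naive agglomerator for ≤ 7 leaves. Complete linkage
makes merge heights monotone, which is asserted. Trees export to Newick
with branch lengths equal to parent-minus-child merge heights; flat
cuts undo the k − 1 highest merges.

## Synthetic data

The generator emulates the study's statistical structure, not its
ecophysiology: no weather, stomatal or photosynthesis process model, just
per-group Gaussian (or moment-matched lognormal, for the strictly positive
biochemical markers) draws around configured means. Defaults are the
published group mean ± SE values for the three species (eight fluorescence
traits at n = 12, five biochemical markers at n = 3). SE → SD conversion
uses the trait class's published replicate count (sd = SE·√n_ref) even when
a different number of replicates is simulated, so noise stays on the
published scale. Structural traits and total proteins were published only
graphically; their cells are missing-flagged placeholders that users can
fill, so default synthetic tables carry 13 of the 17 traits. Two published
SE cells print as 0.00 and are used verbatim, giving (near-)degenerate
simulated cells rather than an invented noise floor.

Traits are drawn independently within a replicate — a known limitation:
real cross-trait correlations (e.g. TBARS with proline) would change THRI
variance, so calibration results transfer to real data only to the extent
that correlations are weak. An effect multiplier scales urban-minus-control
mean differences (0 = no condition effect), and `null_model` flattens all
four groups of a species onto its control-June means for type-I error
studies. Identical configuration and seed reproduce tables bit-for-bit.

On this synthetic design, the composite index reproduces the qualitative
published ordering: with 3 pseudo-replicates per group and within-species
scope, every species' group-mean THRI is lower in urban-August than in
control-June, and *Tilia* shows the largest decline in ≈ 99% of simulated
seasons (the acceptance suite requires ≥ 90% over 200 seeds). At raw
replicate level, where 9 of 12 replicates carry no biochemistry, the
biochemical block is down-weighted and the ordering is less stable (≈ 80%)
— one reason the pseudo-replicate mode exists. Passing these tests shows
the pipeline's internal consistency under its own statistical assumptions;
it does not validate the index against independently measured tree
vitality.

## Numerical choices and problem sizes

Values parse via Python's `float` for exact write/read round-trips.
Reported p values may underflow to 0 for extreme F; codes treat that as
p < 0.001. The test suite and the acceptance script size their simulations
to run comfortably on a single CPU: 200 seeded seasons for the ordering
property, 2000 null simulations for calibration, brute-force clustering
oracles at ≤ 7 leaves, and ≤ 2×2×8 factorial oracles.
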