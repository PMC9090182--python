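# Methods

## Connectivity metrics

Five pairwise association metrics define network edges.  Pearson, Spearman
(average ranks for ties), Kendall tau-b (tie-corrected) and cosine
similarity delegate to scipy/numpy primitives; their identities — Pearson =
cosine of centred vectors, Spearman = Pearson of ranks — are enforced as
tests.  A zero-variance (constant) ROI signal makes the correlation metrics
undefined; the value is never silently set to 0 — a `MetricUndefinedError`
names the offending ROI pair (and window, for dynamic networks), because a
constant edge column would otherwise quietly degrade every downstream
filter statistic.  Matrices are stored dense; only the upper triangle is
computed and mirrored, since symmetry is an invariant of the construction,
not a storage optimization.

## Maximal information coefficient

MIC is the maximum over all axis-aligned grids with `rows·cols ≤ B(n)`,
`B(n) = floor(n^0.6)`, of the gridded mutual information divided by
`log2 min(rows, cols)`.  Note that the simpler "MI over the smaller marginal
entropy" normalization sometimes quoted for MIC is not what the canonical
MINE statistic computes; this package implements the canonical grid-maximum
definition.  `B(n)` is floored at 4 so that the minimal 2×2 grid is always
admissible (otherwise n in 8..10 would admit no grid at all).

The default search follows the MINE approximation — equipartition one axis
into l rows, optimize the other axis by dynamic programming over *clumps*
(maximal runs of points, in axis order, that an optimal cut never splits:
tied values are atomic and same-row runs merge losslessly), limited to
`clump_factor·k` superclumps — with two refinements:

* **coordinate ascent** (`ascent_iterations`, default 3; `ascent_starts`
  deterministic starting partitions, default 3): after the initial pass the
  roles alternate, each axis re-optimized by the same DP against the
  other's current partition, stopping early at a fixed point.  Every grid
  scored is admissible, so the result can never exceed the true maximum;
* **bounded exhaustion** (`enum_cost_budget`, default 2·10⁶): when an axis
  has few enough tie-respecting cut sets that `n_cut_sets·n² ` fits the
  budget, all of its l-row partitions are enumerated and the DP (run
  without superclump truncation, where it is provably optimal) solves the
  other axis exactly.  Every grid shape whose smaller dimension is
  enumerable is then solved exactly; at desk scale (n ≤ ~40, B ≤ 9) this
  covers all admissible shapes, and at fMRI scale (n = 137, B = 19) the
  search smoothly degrades to the ascent approximation.

Both axis orientations are evaluated and the larger value returned, which
also enforces symmetry in the arguments.  An independent `exact_mode`
enumerates *every* admissible grid (cuts between distinct sorted values on
both axes, MI vectorized over cut combinations); it is the oracle in tests
and is feasible only for small n.  Because the approximate search only ever
scores admissible grids, `approx ≤ exact` holds unconditionally.  The inner
loops are numba-compiled with an identical pure-Python fallback.

Determinism: ties are ordered by stable sorts, starting partitions are
fixed quantile shifts, and no randomness enters the search.  MIC therefore
depends on the data only through orderings, giving exact invariance under
strictly increasing transforms of either argument.

Constant vectors carry no information: MIC returns 0 with a warning rather
than an error, so an all-flat ROI degrades a network to zero edges instead
of aborting a cohort run (the correlation metrics, whose value would be
0/0, still fail loudly).

## Dynamic networks

Windows use 0-based, half-open coordinates: window k covers volumes
`[k·step, k·step + size)`; trailing volumes that do not fill a complete
window are dropped, matching `floor((num_volume − size)/step) + 1` (137
volumes at size 50, step 8 give exactly 11 windows).  The per-window
connectivity squares are averaged element-wise as-is — deliberately without
a Fisher z transform, which the underlying protocol does not apply — so
every averaged entry stays inside the per-window min/max envelope.  The
default sweep grid is size ∈ {50, 70, 90, 110}, step ∈ {1, 2, 4, 8, 10}.

## Features and filters

The default flatten keeps the strict upper triangle (p = R(R−1)/2
features): the full-square flatten duplicates every edge and carries the
constant unit diagonal, which is degenerate under every univariate test.
`full_square` remains available for literal replication; both layouts are
inverted exactly by `reporting.index_to_pair`.

Filters are two-sided two-sample tests per feature: pooled-variance Student
t (Welch by flag), Wilcoxon rank-sum (exact U null for tie-free columns
with total n ≤ 30 where enumeration is cheap and the normal approximation
weakest, tie-corrected normal approximation otherwise), and two-sample
Kolmogorov–Smirnov with the asymptotic p-value.  Selection keeps features
with p strictly below the threshold; constant columns get p = 1 and a
degenerate flag.  No multiple-testing correction is applied by default —
the replicated protocol thresholds raw p-values — but Benjamini–Hochberg is
available (`correction="bh"`).  Selection is monotone in the threshold and
equivariant under feature permutations; both are property-tested.

## Classification and evaluation

Base estimators are linear-kernel SVMs (libsvm via scikit-learn), C = 1.0
by default (the protocol does not state a value; the conventional default is
used and configurable).  Decision scores are fused raw — no per-estimator
normalization, matching the plain linear fusion of the protocol; a z-score
option exists but is off by default.  A fused score of exactly 0 predicts
the control class (deterministic, conservative toward controls).  MCI is
the positive class (label 1), NC negative (label 0).

LOOCV recomputes the filter inside every training fold, so the held-out
subject never influences selection.  The per-metric decision scores do not
depend on α, so one pass over the folds serves the entire α grid; the grid
report always carries the full 9-row table plus the argmax, never the
argmax alone, because a post-hoc best-α is an optimistic estimate — the
nested two-level LOOCV (inner folds pick (α, threshold), ties to the
smaller α then the smaller threshold) is the honest counterpart.  An
optional audit log records the exact subject sets used by every filter and
training call at both levels; the test suite asserts the outer held-out
subject never appears in an inner-level call.

An empty feature selection (possible under strict thresholds on null data)
degrades the estimator to a flagged majority-class constant scorer rather
than failing the fold.

Caveat observed in simulation: at small n with class-balanced LOOCV and
label-free (null or permuted) features, accuracy sits *below* 0.5 — removing
the test subject leaves its class in the training minority, so a no-signal
classifier systematically predicts the other class.  This well-known
LOOCV anti-learning bias is why the permutation test asserts "no spurious
skill" rather than a symmetric chance band; the balanced 20+20 null cohort
with empty selections lands at exactly 0.5 via the majority fallback.

## Synthetic cohorts

The generator emulates the *output shape* of a preprocessed resting-state
fMRI cohort: per subject a num_ROI × num_volume matrix of mean ROI signals,
two groups, binary labels.  Controls draw stationary Gaussians with a
block-diagonal correlation matrix (blocks of 5 ROIs at ρ = 0.1, a mild
stand-in for intra-network coherence); patients differ only on the planted
edges — disjoint cross-block pairs, baseline correlation 0 — either by a
linear shift of +`effect_delta` on the correlation (default 0.5) or, in
quadratic mode, by replacing the partner ROI with the standardized square
of its mate plus Gaussian noise (`quad_noise` = 0.5 sd before
re-standardization): an association with population Pearson correlation 0
that MIC detects.  Temporal smoothness comes from a shared AR(1) filter
(coefficient 0.3, a mild default; the filter form `x_t = a·x_{t−1} +
sqrt(1−a²)·e_t` preserves the cross-ROI correlation exactly, verified
against the target matrix on a 10 000-volume draw).  Positive definiteness
after planting is repaired deterministically by flooring eigenvalues at
1e−6 and renormalizing to unit diagonal.

Default scale is 20 subjects per group, 20 ROIs, 137 volumes (140 acquired
minus 3 discarded for magnetization equilibrium) and 10 planted edges: the
full atlas width (116 ROIs) and cohort size are expressible but the default
keeps the MIC hotspot — all pairs × all subjects — at desk speed.  What the
generator does **not** model: hemodynamic response shape, scanner noise and
drifts, motion artifacts, spatial structure within ROIs, inter-subject
covariance heterogeneity.  Passing tests therefore demonstrate the
pipeline's statistical machinery (recovery of known differential edges,
calibrated null behavior, MIC's nonlinear sensitivity), not performance on
real scans.

The quadratic-coupling evaluation uses static (single-window) networks:
the complementarity claim under test concerns the metric, not the
windowing, and MIC over all windows × pairs × subjects is the pipeline's
cost hotspot.

## Numerical choices and degenerate inputs

* Correlation values are clipped to [−1, 1] against floating-point
  overshoot; MIC to [0, 1].
* Frequency-ranking ties break by ascending feature index; ROI aggregation
  credits both endpoints of each selected edge, so per-ROI counts sum to
  exactly twice the per-edge counts (tested conservation identity).  How a
  "top ROI" is derived from edge features is a declared convention of this
  package; edges and ROI aggregates are always reported separately.
* Evaluation JSON validates against `result_schema.json` shipped in the
  package; provenance records the config hash and library versions, and
  contains no timestamps so identical configs produce byte-identical
  output.
* Subject files are TSV (ROIs as rows, volumes as columns, optional label
  column); the manifest carries a format-version tag and label vocabulary
  {MCI, NC}; all subjects must share one shape, violations name the
  offending subject.

## Known limitations

* The MIC search is exact only where the enumeration budget reaches; above
  it the coordinate ascent inherits the MINE approximation's lack of a
  global guarantee (always from below).
* LOOCV decision values from libsvm carry solver tolerance (~1e−3); label
  symmetry and shuffle invariance hold to that tolerance.
* The rank-sum exact/asymptotic switch at n = 30 is a pragmatic cut, not a
  statistical optimum.
* Nested LOOCV is O(n²) model fits per candidate; at the default cohort
  scale this is seconds, at 137 subjects × full grids it is the slowest
  protocol in the package.
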