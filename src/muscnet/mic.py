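"""Maximal information coefficient (MIC) computed from scratch.

MIC scores the association between two real vectors by gridding the
scatterplot: for every grid with ``rows * cols <= B(n)`` (the resolution
budget, ``B(n) = floor(n ** alpha_exponent)``), the mutual information of the
induced 2-D histogram is divided by ``log2(min(rows, cols))``; MIC is the
maximum of this normalized value over all admissible grids.  A noiseless
functional relationship — linear or not — saturates the normalizer and
scores 1, which is why MIC complements Pearson-style metrics on nonlinear
couplings.  MIC depends on the data only through orderings, so it is
invariant under strictly increasing transforms of either argument.

Two search strategies are provided:

* the default approximate search equipartitions one axis and optimizes the
  other by dynamic programming over "clumps" (maximal runs of points that no
  optimal cut separates) — the standard MINE approximation — then refines
  the result by coordinate ascent, alternately re-optimizing each axis
  while the other is held fixed.  Both orientations are evaluated.  Every
  grid it scores is admissible, so the result never exceeds the true
  maximum;
* ``exact_mode`` exhaustively enumerates every admissible grid whose cuts
  fall between distinct data values.  It is feasible only for small ``n``
  and small budgets and serves as the independent oracle for the
  approximate search.

The approximate search is JIT-compiled with numba when available and falls
back to the identical pure-Python code path otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class MicParams:
    """Tuning knobs of the MIC grid search.

    alpha_exponent
        Exponent of the grid-resolution budget ``B(n) = floor(n**alpha)``;
        0.6 is the canonical default.  The budget is floored at 4 so the
        minimal 2x2 grid is always admissible.
    clump_factor
        The optimized axis considers at most ``clump_factor * k`` candidate
        cut blocks when searching a k-column partition (the superclump
        limit); 15 is the canonical default.
    ascent_iterations
        Rounds of coordinate-ascent refinement after the initial
        equipartition-based pass; 3 by default.  0 reproduces the plain
        MINE approximation.
    ascent_starts
        Number of deterministic starting partitions per row count: the MINE
        equipartition plus shifted quantile partitions.  Multiple starts
        guard the ascent against local optima; 3 by default.
    enum_cost_budget
        When one axis has few enough distinct cut sets that
        ``n_cut_sets * n**2`` stays within this budget, that axis is
        enumerated exhaustively (with untruncated DP on the other axis),
        making the search exact for every grid shape whose smaller
        dimension is enumerable.  Larger problems fall back to the
        equipartition-plus-ascent approximation.  Default 2e6.
    exact_mode
        Exhaustively enumerate all admissible grids instead of the
        approximate search.  Cost grows combinatorially; intended for
        small-n oracle checks only.
    """

    alpha_exponent: float = 0.6
    clump_factor: int = 15
    ascent_iterations: int = 3
    ascent_starts: int = 3
    enum_cost_budget: float = 2e6
    exact_mode: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_exponent <= 1.0):
            raise InputError("alpha_exponent must lie in (0, 1]")
        if self.clump_factor < 1:
            raise InputError("clump_factor must be a positive integer")
        if self.ascent_iterations < 0:
            raise InputError("ascent_iterations must be >= 0")
        if self.ascent_starts < 1:
            raise InputError("ascent_starts must be >= 1")

    def budget(self, n: int) -> int:
        """Grid budget B(n); at least 4 so a 2x2 grid always fits."""
        return max(4, int(math.floor(n ** self.alpha_exponent)))


@dataclass(frozen=True)
class MicGridScore:
    """Normalized mutual information of one explicit grid."""

    rows_x: int
    cols_y: int
    normalized_mi: float


# ---------------------------------------------------------------------------
# approximate search (compiled kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _equip_nb(groups: np.ndarray, l: int) -> np.ndarray:  # pragma: no cover
    """Assign pre-sorted points to <= l near-equal bins, never splitting ties.

    ``groups`` marks tie groups along the sorted axis.  The desired bin size
    is re-estimated from the remaining points whenever a bin closes (the
    MINE equipartition rule).
    """
    n = groups.shape[0]
    out = np.empty(n, dtype=np.int64)
    i = 0
    row = 0
    curr = 0
    desired = n / l
    while i < n:
        j = i
        while j < n and groups[j] == groups[i]:
            j += 1
        s = j - i
        if curr != 0 and abs(curr + s - desired) >= abs(curr - desired):
            row += 1
            curr = 0
            rem = l - row
            if rem >= 1:
                desired = (n - i) / rem
        for t in range(i, j):
            out[t] = row
        curr += s
        i = j
    return out


@njit(cache=True)
def _clumps_nb(groups: np.ndarray, q: np.ndarray, max_clumps: int) -> np.ndarray:  # pragma: no cover
    """Clump boundaries (cumulative counts) along one axis.

    A clump is a maximal run, in axis order, that an optimal cut never
    separates: tied axis values are atomic, and consecutive atoms whose
    points share a single row of ``q`` are merged.  If more than
    ``max_clumps`` clumps result, they are re-binned into at most that many
    superclumps of near-equal point count (the approximation step).
    """
    n = groups.shape[0]
    # atomic tie blocks with row label (-1 = mixed)
    ends = np.empty(n + 1, dtype=np.int64)
    labels = np.empty(n, dtype=np.int64)
    nb = 0
    i = 0
    while i < n:
        j = i
        while j < n and groups[j] == groups[i]:
            j += 1
        lab = q[i]
        for t in range(i + 1, j):
            if q[t] != lab:
                lab = -1
                break
        labels[nb] = lab
        ends[nb] = j
        nb += 1
        i = j
    bounds = np.empty(nb + 1, dtype=np.int64)
    bounds[0] = 0
    m = 0
    for b in range(nb):
        last = b == nb - 1
        if last or labels[b] == -1 or labels[b + 1] == -1 or labels[b] != labels[b + 1]:
            m += 1
            bounds[m] = ends[b]
    bounds = bounds[: m + 1]
    if m <= max_clumps:
        return bounds
    # superclumps: equipartition the clump-id sequence
    clump_id = np.empty(n, dtype=np.int64)
    for c in range(m):
        for t in range(bounds[c], bounds[c + 1]):
            clump_id[t] = c
    sup = _equip_nb(clump_id, max_clumps)
    out = np.empty(max_clumps + 1, dtype=np.int64)
    out[0] = 0
    mm = 0
    for t in range(1, n):
        if sup[t] != sup[t - 1]:
            mm += 1
            out[mm] = t
    mm += 1
    out[mm] = n
    return out[: mm + 1]


@njit(cache=True)
def _dp_nb(bounds: np.ndarray, q: np.ndarray, nrows: int, kmax: int, n: int):  # pragma: no cover
    """Best column partitions over clump boundaries for 2..kmax columns.

    Mutual information decomposes additively over columns as
    I = H(Q) + sum_j [ (sum_q (a_jq/n) ln(a_jq/n)) - (s_j/n) ln(s_j/n) ],
    so an interval DP finds the optimum for every column count at once.
    Returns (vals, assign): ``vals[c-2]`` is the best I (nats) over exactly
    c columns, ``assign[c-2]`` the per-point column index achieving it.
    """
    m = bounds.shape[0] - 1
    # cumulative per-row counts at clump boundaries
    cum = np.zeros((m + 1, nrows), dtype=np.float64)
    for t in range(1, m + 1):
        for r in range(nrows):
            cum[t, r] = cum[t - 1, r]
        for p in range(bounds[t - 1], bounds[t]):
            cum[t, q[p]] += 1.0

    hq = 0.0
    for r in range(nrows):
        prob = cum[m, r] / n
        if prob > 0.0:
            hq -= prob * math.log(prob)

    kk = min(kmax, m)
    g = np.full((m + 1, m + 1), -np.inf)
    for s in range(m + 1):
        for t in range(s + 1, m + 1):
            tot = 0.0
            acc = 0.0
            for r in range(nrows):
                a = cum[t, r] - cum[s, r]
                tot += a
                if a > 0.0:
                    acc += (a / n) * math.log(a / n)
            g[s, t] = acc - (tot / n) * math.log(tot / n)

    nk = max(kmax - 1, 1)
    vals = np.full(nk, -np.inf)
    assign = np.zeros((nk, n), dtype=np.int64)
    f_prev = np.full(m + 1, -np.inf)
    parent = np.zeros((m + 1, kk + 1), dtype=np.int64)
    for t in range(1, m + 1):
        f_prev[t] = g[0, t]
    for ncols in range(2, kk + 1):
        f_curr = np.full(m + 1, -np.inf)
        for t in range(ncols, m + 1):
            bb = -np.inf
            arg = ncols - 1
            for s in range(ncols - 1, t):
                v = f_prev[s] + g[s, t]
                if v > bb:
                    bb = v
                    arg = s
            f_curr[t] = bb
            parent[t, ncols] = arg
        val = f_curr[m] + hq
        if val < 0.0:
            val = 0.0
        vals[ncols - 2] = val
        # backtrack the boundary chain for this column count
        cuts = np.empty(ncols + 1, dtype=np.int64)
        cuts[ncols] = m
        t = m
        for c in range(ncols, 1, -1):
            t = parent[t, c]
            cuts[c - 1] = t
        cuts[0] = 0
        for c in range(ncols):
            for p in range(bounds[cuts[c]], bounds[cuts[c + 1]]):
                assign[ncols - 2, p] = c
        f_prev = f_curr
    return vals, assign


@njit(cache=True)
def _quantile_rows_nb(groups: np.ndarray, l: int, offset: float) -> np.ndarray:  # pragma: no cover
    """Row assignment from quantile cuts shifted by ``offset`` of a bin width.

    Cut positions are snapped forward past tie groups so tied values are
    never split.  Used as alternative ascent starting points.
    """
    n = groups.shape[0]
    out = np.zeros(n, dtype=np.int64)
    row = 0
    pos = 0
    for i in range(1, l):
        cut = int((i + offset) * n / l)
        if cut <= pos:
            cut = pos + 1
        if cut >= n:
            break
        # snap forward so the cut sits on a tie-group boundary
        while cut < n and groups[cut] == groups[cut - 1]:
            cut += 1
        if cut >= n or cut <= pos:
            continue
        for t in range(pos, cut):
            out[t] = row
        row += 1
        pos = cut
    for t in range(pos, n):
        out[t] = row
    return out


@njit(cache=True)
def _mic_core(gx: np.ndarray, gy: np.ndarray, perm_y: np.ndarray,
              budget: int, clump_factor: int, iters: int,
              starts: int, enum_budget: float) -> float:  # pragma: no cover
    """Full approximate search over all admissible grid shapes.

    Arrays live in x-sorted order; ``perm_y[t]`` is the x-order position of
    the point ranked t on the y axis.  For every row count l, either every
    tie-respecting l-row partition of the y axis is enumerated (when the
    cost bound allows — exact for those shapes) or the y axis starts from
    the MINE equipartition (plus shifted quantile partitions when
    ``starts`` > 1) and coordinate ascent re-optimizes each axis in turn.
    The x axis is always optimized by DP.  Both orientations are covered by
    running the caller twice with axes swapped.
    """
    n = gx.shape[0]
    best = 0.0
    lmax = budget // 2
    # candidate y cut positions: boundaries between tie groups, in y order
    ygaps = np.empty(n - 1, dtype=np.int64)
    ng = 0
    for t in range(1, n):
        if gy[t] != gy[t - 1]:
            ygaps[ng] = t
            ng += 1
    for l in range(2, lmax + 1):
        k = budget // l
        if k < 2:
            break
        r = l - 1
        if ng < r:
            continue  # fewer distinct y values than rows: no such grid
        n_combos = 1.0
        for i in range(r):
            n_combos = n_combos * (ng - i) / (i + 1)
        if n_combos * n * n <= enum_budget:
            # exhaustive: every tie-respecting l-row partition of y
            idx = np.arange(r)
            q_y = np.empty(n, dtype=np.int64)
            q_x = np.empty(n, dtype=np.int64)
            while True:
                row = 0
                c = 0
                for t in range(n):
                    if c < r and t == ygaps[idx[c]]:
                        row += 1
                        c += 1
                    q_y[t] = row
                for t in range(n):
                    q_x[perm_y[t]] = q_y[t]
                bounds = _clumps_nb(gx, q_x, n)  # no truncation: DP stays exact
                vals, _ = _dp_nb(bounds, q_x, l, k, n)
                kk = min(k, bounds.shape[0] - 1)
                for cc in range(2, kk + 1):
                    v = vals[cc - 2] / math.log(min(cc, l))
                    if v > best:
                        best = v
                pos = r - 1
                while pos >= 0 and idx[pos] == ng - r + pos:
                    pos -= 1
                if pos < 0:
                    break
                idx[pos] += 1
                for t in range(pos + 1, r):
                    idx[t] = idx[t - 1] + 1
            continue
        for s in range(starts):
            if s == 0:
                q_y = _equip_nb(gy, l)
            else:
                q_y = _quantile_rows_nb(gy, l, (s - 0.5 * (starts - 1)) / starts)
            q_x = np.empty(n, dtype=np.int64)
            for t in range(n):
                q_x[perm_y[t]] = q_y[t]
            rows = int(q_x.max()) + 1
            if rows < 2:
                continue
            last_val = -1.0
            for it in range(iters + 1):
                bounds = _clumps_nb(gx, q_x, clump_factor * k)
                vals, assign = _dp_nb(bounds, q_x, rows, k, n)
                kk = min(k, bounds.shape[0] - 1)
                best_c = -1
                best_cv = -1.0
                for c in range(2, kk + 1):
                    v = vals[c - 2] / math.log(min(c, rows))
                    if v > best:
                        best = v
                    if v > best_cv:
                        best_cv = v
                        best_c = c
                if best_c < 0 or it == iters:
                    break
                # re-optimize the y axis against the chosen column partition
                col_y = np.empty(n, dtype=np.int64)
                for t in range(n):
                    col_y[t] = assign[best_c - 2, perm_y[t]]
                bounds_y = _clumps_nb(gy, col_y, clump_factor * l)
                vals_y, assign_y = _dp_nb(bounds_y, col_y, best_c, l, n)
                ll = min(l, bounds_y.shape[0] - 1)
                best_r = -1
                best_rv = -1.0
                for r in range(2, ll + 1):
                    v = vals_y[r - 2] / math.log(min(r, best_c))
                    if v > best:
                        best = v
                    if v > best_rv:
                        best_rv = v
                        best_r = r
                if best_r < 0:
                    break
                round_val = best_cv if best_cv > best_rv else best_rv
                if round_val <= last_val + 1e-12:
                    break  # ascent converged
                last_val = round_val
                for t in range(n):
                    q_x[perm_y[t]] = assign_y[best_r - 2, t]
                rows = int(q_x.max()) + 1
                if rows < 2:
                    break
    return best


def _tie_groups(sorted_values: np.ndarray) -> np.ndarray:
    """Group ids such that equal consecutive sorted values share an id."""
    groups = np.zeros(sorted_values.shape[0], dtype=np.int64)
    groups[1:] = np.cumsum(np.diff(sorted_values) != 0)
    return groups


def _mic_approx(x: np.ndarray, y: np.ndarray, budget: int, params: MicParams) -> float:
    n = x.shape[0]
    best = 0.0
    for a, b in ((x, y), (y, x)):
        order_a = np.argsort(a, kind="stable")
        a_sorted = a[order_a]
        b_along_a = b[order_a]
        perm_b = np.argsort(b_along_a, kind="stable").astype(np.int64)
        ga = _tie_groups(a_sorted)
        gb = _tie_groups(b_along_a[perm_b])
        val = _mic_core(ga, gb, perm_b, budget,
                        params.clump_factor, params.ascent_iterations,
                        params.ascent_starts, params.enum_cost_budget)
        best = max(best, float(val))
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

def _mic_exact(xv: np.ndarray, yv: np.ndarray, budget: int) -> float:
    """Exhaustive maximum over all admissible grids.

    Cut candidates are the gaps between distinct sorted values on each axis
    (a grid can never split tied values).  For each (cols, rows) shape with
    cols*rows <= budget, every cut combination is scored; the MI evaluation
    is vectorized over all x-cut combinations.
    """
    n = xv.shape[0]
    order_x = np.argsort(xv, kind="stable")
    order_y = np.argsort(yv, kind="stable")
    x_gaps = np.nonzero(np.diff(xv[order_x]))[0] + 1  # admissible cuts, in counts
    y_gaps = np.nonzero(np.diff(yv[order_y]))[0] + 1
    pos_y = np.empty(n, dtype=np.int64)
    pos_y[order_y] = np.arange(n)

    best = 0.0
    for rows in range(2, budget // 2 + 1):
        max_cols = budget // rows
        if max_cols < 2:
            break
        if len(y_gaps) < rows - 1:
            continue
        for ycuts in itertools.combinations(y_gaps.tolist(), rows - 1):
            row_of_point = np.searchsorted(np.asarray(ycuts), pos_y, side="right")
            onehot = np.zeros((n, rows))
            onehot[np.arange(n), row_of_point] = 1.0
            cum = np.zeros((n + 1, rows))
            cum[1:] = np.cumsum(onehot[order_x], axis=0)
            row_tot = cum[n]
            pr = row_tot[row_tot > 0] / n
            hq = -np.sum(pr * np.log(pr))
            for cols in range(2, max_cols + 1):
                if len(x_gaps) < cols - 1:
                    break
                combos = np.asarray(
                    list(itertools.combinations(x_gaps.tolist(), cols - 1)), dtype=np.int64
                )
                bounds = np.concatenate(
                    [
                        np.zeros((combos.shape[0], 1), dtype=np.int64),
                        combos,
                        np.full((combos.shape[0], 1), n, dtype=np.int64),
                    ],
                    axis=1,
                )
                joint = cum[bounds[:, 1:]] - cum[bounds[:, :-1]]  # (N, cols, rows)
                col_tot = joint.sum(axis=2)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pj = joint / n
                    term_joint = np.where(joint > 0, pj * np.log(pj), 0.0).sum(axis=(1, 2))
                    pc = col_tot / n
                    term_col = np.where(col_tot > 0, pc * np.log(pc), 0.0).sum(axis=1)
                mi = hq + term_joint - term_col
                val = float(mi.max()) / math.log(min(rows, cols))
                if val > best:
                    best = val
    return min(best, 1.0)


def mic(x, y, params: MicParams | None = None) -> float:
    """Maximal information coefficient of two equal-length vectors.

    Returns a value in [0, 1].  A constant input vector carries no
    information: the value is 0 and a warning is emitted.  Symmetry is
    enforced by evaluating both axis orientations and taking the maximum.
    """
    params = params or MicParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise InputError("mic expects two 1-D vectors of equal length")
    n = x.shape[0]
    if n < 8:
        raise InputError(f"mic requires at least 8 samples, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("mic inputs contain non-finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("mic of a constant vector is 0", stacklevel=2)
        return 0.0
    b = params.budget(n)
    if params.exact_mode:
        return _mic_exact(x, y, b)
    return _mic_approx(x, y, b, params)


# ---------------------------------------------------------------------------
# explicit-grid scoring
# ---------------------------------------------------------------------------

def normalized_mi_from_counts(counts) -> float:
    """Normalized MI (bits over log2 of the smaller bin count) of a table."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError("need a 2-D contingency table with >= 2 bins per axis")
    n = counts.sum()
    if n <= 0:
        raise InputError("empty contingency table")
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / outer), 0.0)
    mi_bits = float(terms.sum())
    return mi_bits / math.log2(min(counts.shape))


def normalized_mi_for_grid(x, y, x_edges, y_edges) -> MicGridScore:
    """Score one explicit grid: MI of the induced histogram over its normalizer.

    ``x_edges``/``y_edges`` are monotone bin-edge sequences covering every
    point (outermost edges inclusive).  A point outside the edges violates
    the contract and raises :class:`InputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if x_edges.shape[0] < 3 or y_edges.shape[0] < 3:
        raise InputError("each axis partition needs at least 2 bins")
    if (
        x.min() < x_edges[0]
        or x.max() > x_edges[-1]
        or y.min() < y_edges[0]
        or y.max() > y_edges[-1]
    ):
        raise InputError("every point must fall inside the grid")
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    return MicGridScore(
        rows_x=x_edges.shape[0] - 1,
        cols_y=y_edges.shape[0] - 1,
        normalized_mi=normalized_mi_from_counts(counts),
    )
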