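"""Connectivity feature vectors and filter feature selection.

Each subject's connectivity square is flattened to a feature vector; a
univariate two-sample test (Student t, Wilcoxon rank-sum, or two-sample
Kolmogorov-Smirnov) scores every feature against the group labels, and the
features with p-value strictly below the threshold are kept.

The default layout keeps only the strict upper triangle: the full-square
flatten duplicates every edge and carries the constant unit diagonal, which
is degenerate under every test.  ``full_square`` remains available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix, SubjectTimeSeries, static_bfcn
from .dynamics import SlidingWindowConfig, dynamic_bfcn
from .errors import InputError

LAYOUTS = ("upper_triangle", "full_square")
FILTER_METHODS = ("Ttest", "Wtest", "KStest")


@dataclass
class FeatureVector:
    subject_id: str | None
    values: np.ndarray
    layout: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.layout not in LAYOUTS:
            raise InputError(f"unknown layout {self.layout!r}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature values contain non-finite entries")


def layout_length(num_roi: int, layout: str) -> int:
    if layout == "full_square":
        return num_roi * num_roi
    if layout == "upper_triangle":
        return num_roi * (num_roi - 1) // 2
    raise InputError(f"unknown layout {layout!r}")


def flatten(cm: ConnectivityMatrix, layout: str = "upper_triangle") -> FeatureVector:
    """Flatten a connectivity square to the chosen feature layout.

    ``full_square`` is a row-major flatten of the whole matrix;
    ``upper_triangle`` keeps entries (i, j) with i < j in row-major pair
    order.  Both are inverted exactly by :func:`muscnet.reporting.index_to_pair`.
    """
    if layout == "full_square":
        vals = cm.values.ravel().copy()
    elif layout == "upper_triangle":
        iu = np.triu_indices(cm.num_roi, k=1)
        vals = cm.values[iu].copy()
    else:
        raise InputError(f"unknown layout {layout!r}")
    return FeatureVector(subject_id=cm.subject_id, values=vals, layout=layout)


def unflatten(values: np.ndarray, num_roi: int, layout: str = "upper_triangle") -> np.ndarray:
    """Rebuild the symmetric square (unit diagonal for upper_triangle)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != layout_length(num_roi, layout):
        raise InputError("value length does not match layout")
    if layout == "full_square":
        return values.reshape(num_roi, num_roi).copy()
    out = np.eye(num_roi)
    iu = np.triu_indices(num_roi, k=1)
    out[iu] = values
    out[(iu[1], iu[0])] = values
    return out


def feature_matrix(
    subjects: list[SubjectTimeSeries],
    metric: str,
    window: SlidingWindowConfig | None = None,
    layout: str = "upper_triangle",
    mic_params=None,
) -> np.ndarray:
    """Stack one flattened (static or dynamic) BFCN per subject.

    With ``window=None`` the static network over the whole series is used;
    otherwise the sliding-window average.
    """
    rows = []
    for ts in subjects:
        if window is None:
            cm = static_bfcn(ts, metric, mic_params=mic_params)
        else:
            cm = dynamic_bfcn(ts, metric, window, mic_params=mic_params)
        rows.append(flatten(cm, layout).values)
    return np.vstack(rows)


@dataclass
class FilterResult:
    method: str
    pvalues: np.ndarray
    threshold: float
    selected: np.ndarray  # sorted feature indices
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _split_groups(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise InputError("X must be subjects x features with one label per subject")
    a = X[y == 1]
    b = X[y == 0]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InputError("each class needs at least 2 subjects")
    return a, b


def _degenerate_mask(X: np.ndarray) -> np.ndarray:
    return np.ptp(np.asarray(X, dtype=float), axis=0) == 0


def ttest_pvalues(X, y, equal_var: bool = True) -> np.ndarray:
    """Two-sided two-sample t-test p-value per feature column.

    Pooled-variance Student test by default (``equal_var=False`` for Welch).
    Features with no variation anywhere get p = 1.
    """
    a, b = _split_groups(X, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var).pvalue
    p = np.where(np.isnan(p), 1.0, p)
    p[_degenerate_mask(X)] = 1.0
    return p


def ranksum_pvalues(X, y) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value per feature.

    The exact U null is used for tie-free columns of small total size
    (n <= 30, where enumeration is cheap and the normal approximation is
    weakest); otherwise the tie-corrected normal approximation.
    """
    a, b = _split_groups(X, y)
    p = np.ones(X.shape[1])
    degen = _degenerate_mask(X)
    small = a.shape[0] + b.shape[0] <= 30
    for j in range(X.shape[1]):
        if degen[j]:
            continue
        col = np.concatenate([a[:, j], b[:, j]])
        method = "exact" if small and np.unique(col).size == col.size else "asymptotic"
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided", method=method)
        p[j] = 1.0 if np.isnan(res.pvalue) else res.pvalue
    return p


def ks_pvalues(X, y) -> np.ndarray:
    """Two-sample two-sided Kolmogorov-Smirnov asymptotic p-value per feature."""
    a, b = _split_groups(X, y)
    p = np.ones(X.shape[1])
    degen = _degenerate_mask(X)
    for j in range(X.shape[1]):
        if degen[j]:
            continue
        res = stats.ks_2samp(a[:, j], b[:, j], alternative="two-sided", method="asymp")
        p[j] = min(res.pvalue, 1.0)
    return p


_FILTERS = {"Ttest": ttest_pvalues, "Wtest": ranksum_pvalues, "KStest": ks_pvalues}


def select(X, y, method: str = "Ttest", threshold: float = 0.05,
           correction: str = "none") -> FilterResult:
    """Filter selection: keep non-degenerate features with p < threshold.

    ``correction="bh"`` applies Benjamini-Hochberg to the p-values first
    (off by default: the published protocol thresholds raw p-values).
    """
    if method not in _FILTERS:
        raise InputError(f"unknown filter method {method!r}; expected one of {FILTER_METHODS}")
    if not (0.0 < threshold <= 1.0):
        raise InputError("threshold must lie in (0, 1]")
    p = _FILTERS[method](X, y)
    if correction == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif correction != "none":
        raise InputError(f"unknown correction {correction!r}")
    degen = _degenerate_mask(X)
    selected = np.nonzero((p < threshold) & ~degen)[0]
    return FilterResult(method=method, pvalues=p, threshold=threshold,
                        selected=selected, degenerate=degen)
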