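"""Selection-frequency reporting: features back to ROI pairs, ranks, overlaps.

Every LOOCV fold selects its own feature subset; counting how often each
feature (connectivity edge) is selected across folds ranks the edges — and,
by crediting both endpoints of each edge, the ROIs — by their stability as
group discriminators.  Two models' top-k lists are compared as a partition
into shared and exclusive features, with each exclusive feature annotated
by its rank in the other model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .features import layout_length
from .models import EvaluationResult


def index_to_pair(flat_index: int, num_roi: int, layout: str = "upper_triangle") -> tuple[int, int]:
    """Invert the feature flatten: flat index -> ROI index pair (i <= j)."""
    if not 0 <= flat_index < layout_length(num_roi, layout):
        raise InputError(f"index {flat_index} out of range for layout {layout!r}")
    if layout == "full_square":
        i, j = divmod(int(flat_index), num_roi)
        return (i, j) if i <= j else (j, i)
    rows, cols = np.triu_indices(num_roi, k=1)
    return int(rows[flat_index]), int(cols[flat_index])


@dataclass
class FrequencyTable:
    feature_counts: np.ndarray  # length = layout feature count
    roi_counts: np.ndarray  # length = num_roi
    layout: str
    num_roi: int
    n_folds: int
    roi_labels: list[str] | None = None

    def ranked_features(self) -> np.ndarray:
        """Feature indices by descending count; ties by ascending index."""
        order = np.lexsort((np.arange(self.feature_counts.size), -self.feature_counts))
        return order

    def top_k(self, k: int) -> np.ndarray:
        if k > self.feature_counts.size:
            raise InputError(f"k={k} exceeds feature count {self.feature_counts.size}")
        return self.ranked_features()[:k]

    def to_dataframe(self) -> pd.DataFrame:
        labels = self.roi_labels or [f"ROI{i}" for i in range(self.num_roi)]
        recs = []
        for idx in self.ranked_features():
            c = int(self.feature_counts[idx])
            if c == 0:
                continue
            i, j = index_to_pair(int(idx), self.num_roi, self.layout)
            recs.append(
                {"feature": int(idx), "roi_i": i, "roi_j": j,
                 "label_i": labels[i], "label_j": labels[j], "count": c}
            )
        return pd.DataFrame(recs, columns=["feature", "roi_i", "roi_j", "label_i", "label_j", "count"])


def frequency_table(
    result: EvaluationResult,
    num_roi: int,
    metric: str | None = None,
    roi_labels: list[str] | None = None,
) -> FrequencyTable:
    """Count per-fold selections of each feature and aggregate onto ROIs.

    ``metric`` picks which estimator's selections to count (defaults to the
    first of the duet).  Each selected edge credits both of its endpoint
    ROIs; a full-square diagonal feature credits its ROI twice, preserving
    the conservation identity sum(roi_counts) == 2 * sum(feature_counts).
    """
    metric = metric or result.config.metric_pair[0]
    layout = result.config.layout
    n_feat = layout_length(num_roi, layout)
    feature_counts = np.zeros(n_feat, dtype=int)
    for fold in result.per_fold_selected:
        if metric not in fold:
            raise InputError(f"no selections recorded for metric {metric!r}")
        feature_counts[np.asarray(fold[metric], dtype=int)] += 1
    roi_counts = np.zeros(num_roi, dtype=int)
    for idx in np.nonzero(feature_counts)[0]:
        i, j = index_to_pair(int(idx), num_roi, layout)
        roi_counts[i] += feature_counts[idx]
        roi_counts[j] += feature_counts[idx]
    return FrequencyTable(
        feature_counts=feature_counts, roi_counts=roi_counts, layout=layout,
        num_roi=num_roi, n_folds=len(result.per_fold_selected), roi_labels=roi_labels,
    )


@dataclass
class OverlapReport:
    k: int
    shared: list[int]
    only_a: list[tuple[int, int]]  # (feature, its rank in table b)
    only_b: list[tuple[int, int]]

    @property
    def overlap_size(self) -> int:
        return len(self.shared)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "shared": self.shared,
            "only_a": [{"feature": f, "rank_in_other": r} for f, r in self.only_a],
            "only_b": [{"feature": f, "rank_in_other": r} for f, r in self.only_b],
            "overlap_size": self.overlap_size,
        }


def top_k_overlap(table_a: FrequencyTable, table_b: FrequencyTable, k: int) -> OverlapReport:
    """Compare two models' top-k features: shared core vs exclusive sets."""
    top_a = table_a.top_k(k)
    top_b = table_b.top_k(k)
    rank_b = {int(f): r for r, f in enumerate(table_b.ranked_features())}
    rank_a = {int(f): r for r, f in enumerate(table_a.ranked_features())}
    set_b = set(int(f) for f in top_b)
    set_a = set(int(f) for f in top_a)
    shared = sorted(set_a & set_b)
    only_a = [(int(f), rank_b[int(f)]) for f in top_a if int(f) not in set_b]
    only_b = [(int(f), rank_a[int(f)]) for f in top_b if int(f) not in set_a]
    return OverlapReport(k=k, shared=shared, only_a=only_a, only_b=only_b)


def plot_top_k(table_a: FrequencyTable, table_b: FrequencyTable, k: int,
               names: tuple[str, str] = ("model A", "model B"), path=None):
    """Side-by-side top-k bar charts; shared features in blue, exclusive in green,
    with each model's own top-k drawn first in red outline order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = top_k_overlap(table_a, table_b, k)
    shared = set(rep.shared)
    fig, axes = plt.subplots(1, 2, figsize=(12, 4))
    for ax, table, name in zip(axes, (table_a, table_b), names):
        top = table.top_k(k)
        colors = ["tab:blue" if int(f) in shared else "tab:green" for f in top]
        ax.bar(range(k), table.feature_counts[top], color=colors, edgecolor="tab:red")
        ax.set_xticks(range(k))
        ax.set_xticklabels([str(int(f)) for f in top], rotation=90, fontsize=7)
        ax.set_title(f"{name}: top-{k} features by selection frequency")
        ax.set_ylabel("folds selected")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
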