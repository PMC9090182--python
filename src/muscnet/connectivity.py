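"""Pairwise correlation metrics and static functional-connectivity networks.

A brain functional connectivity network (BFCN) is a weighted graph whose
nodes are atlas regions of interest (ROIs) and whose edge (i, j) carries a
pairwise association between the BOLD time series of ROI_i and ROI_j.  Five
association metrics are supported:

=======  =====================================  ==========
name     statistic                              range
=======  =====================================  ==========
PCC      Pearson correlation coefficient        [-1, 1]
SCC      Spearman rank correlation              [-1, 1]
KCC      Kendall tau-b (tie-corrected)          [-1, 1]
CS       cosine similarity                      [-1, 1]
MIC      maximal information coefficient        [0, 1]
=======  =====================================  ==========

PCC equals cosine similarity applied to mean-centred vectors; SCC equals
PCC applied to fractional ranks.  MIC lives in :mod:`muscnet.mic`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, MetricUndefinedError

METRICS = ("PCC", "SCC", "KCC", "CS", "MIC")

#: metrics whose value range is [-1, 1]; MIC alone is non-negative
SIGNED_METRICS = ("PCC", "SCC", "KCC", "CS")


@dataclass
class SubjectTimeSeries:
    """One subject's ROI x volume BOLD signal matrix.

    Row ``i`` of ``signals`` is the BOLD vector of ROI_i; column ``m`` is the
    m-th acquired volume after preprocessing.
    """

    subject_id: str
    signals: np.ndarray
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise InputError(f"{self.subject_id}: signals must be a 2-D matrix")
        n_roi, n_vol = self.signals.shape
        if n_roi < 2:
            raise InputError(f"{self.subject_id}: need at least 2 ROIs, got {n_roi}")
        if n_vol < 3:
            raise InputError(f"{self.subject_id}: need at least 3 volumes, got {n_vol}")
        if not np.all(np.isfinite(self.signals)):
            raise InputError(f"{self.subject_id}: signals contain non-finite values")
        if self.roi_labels is not None:
            labels = list(self.roi_labels)
            if len(labels) != n_roi:
                raise InputError(
                    f"{self.subject_id}: {len(labels)} ROI labels for {n_roi} ROIs"
                )
            if len(set(labels)) != n_roi:
                raise InputError(f"{self.subject_id}: ROI labels are not unique")
            self.roi_labels = labels

    @property
    def num_roi(self) -> int:
        return self.signals.shape[0]

    @property
    def num_volume(self) -> int:
        return self.signals.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric num_ROI x num_ROI matrix of pairwise correlation values."""

    metric: str
    values: np.ndarray
    subject_id: str | None = None
    roi_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError("connectivity values must be a square matrix")
        if self.metric not in METRICS:
            raise InputError(f"unknown metric {self.metric!r}; expected one of {METRICS}")

    @property
    def num_roi(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        """Write a TSV square matrix with ROI labels plus a JSON sidecar.

        The sidecar ``<path>.meta.json`` records the metric name and subject id.
        """
        path = Path(path)
        labels = self.roi_labels or [f"ROI{i}" for i in range(self.num_roi)]
        with open(path, "w") as fh:
            fh.write("\t".join([""] + labels) + "\n")
            for lab, row in zip(labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
        meta = {"metric": self.metric, "subject_id": self.subject_id}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        return cls(
            metric=meta["metric"],
            values=np.asarray(rows),
            subject_id=meta.get("subject_id"),
            roi_labels=header,
        )


def _check_pair(x: np.ndarray, y: np.ndarray, min_len: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise InputError("correlation inputs must be 1-D vectors")
    if x.shape[0] != y.shape[0]:
        raise InputError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < min_len:
        raise InputError(f"need at least {min_len} samples, got {x.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("correlation inputs contain non-finite values")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation: centred inner product over the product of norms."""
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        raise MetricUndefinedError("Pearson undefined for a zero-variance vector")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson on average fractional ranks."""
    x, y = _check_pair(x, y)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return pearson(rx, ry)


def kendall(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall rank correlation, tau-b variant (tie-corrected)."""
    x, y = _check_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise MetricUndefinedError("Kendall undefined for a constant vector")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(np.clip(tau, -1.0, 1.0))


def cosine(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine similarity: inner product over the product of Euclidean norms."""
    x, y = _check_pair(x, y)
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise MetricUndefinedError("cosine similarity undefined for a zero vector")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def _metric_fn(metric: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if metric == "MIC":
        # local import avoids a cycle (mic module is self-contained)
        from .mic import mic

        return lambda x, y: mic(x, y)
    return {"PCC": pearson, "SCC": spearman, "KCC": kendall, "CS": cosine}[metric]


def static_bfcn(
    ts: SubjectTimeSeries,
    metric: str,
    mic_params=None,
) -> ConnectivityMatrix:
    """Build a static BFCN: one pairwise correlation per unordered ROI pair.

    The matrix is computed on the upper triangle and mirrored; the diagonal
    holds each metric's self-correlation (exactly 1 for non-constant rows,
    for MIC computed explicitly since ties can lower it below 1).

    Parameters
    ----------
    ts : SubjectTimeSeries
    metric : one of PCC, SCC, KCC, CS, MIC
    mic_params : optional :class:`muscnet.mic.MicParams` when metric == "MIC"
    """
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}; expected one of {METRICS}")
    sig = ts.signals
    n = ts.num_roi
    values = np.empty((n, n), dtype=float)

    # fast vectorised paths: the rank/centring transforms reduce SCC and CS
    # to matrix products; KCC and MIC need the per-pair statistic.
    if metric in ("PCC", "SCC", "CS"):
        if metric == "CS":
            norms = np.linalg.norm(sig, axis=1)
            bad = np.nonzero(norms == 0)[0]
            if bad.size:
                i = int(bad[0])
                raise MetricUndefinedError(
                    f"{ts.subject_id}: cosine undefined, ROI {i} is a zero vector",
                    pair=(i, i),
                )
            values = (sig @ sig.T) / np.outer(norms, norms)
        else:
            data = sig if metric == "PCC" else stats.rankdata(sig, axis=1, method="average")
            centred = data - data.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(centred, axis=1)
            bad = np.nonzero(norms == 0)[0]
            if bad.size:
                i = int(bad[0])
                raise MetricUndefinedError(
                    f"{ts.subject_id}: {metric} undefined, ROI {i} has zero variance",
                    pair=(i, i),
                )
            values = (centred @ centred.T) / np.outer(norms, norms)
        np.clip(values, -1.0, 1.0, out=values)
        np.fill_diagonal(values, 1.0)
        values = (values + values.T) / 2.0  # exact symmetry
    else:
        fn = _metric_fn(metric) if metric != "MIC" else None
        if metric == "MIC":
            from .mic import MicParams, mic

            params = mic_params or MicParams()
            fn = lambda a, b: mic(a, b, params)  # noqa: E731
        for i in range(n):
            for j in range(i, n):
                try:
                    values[i, j] = fn(sig[i], sig[j])
                except MetricUndefinedError as exc:
                    raise MetricUndefinedError(
                        f"{ts.subject_id}: {metric} undefined at ROI pair ({i}, {j}): {exc}",
                        pair=(i, j),
                    ) from exc
                values[j, i] = values[i, j]

    return ConnectivityMatrix(
        metric=metric, values=values, subject_id=ts.subject_id, roi_labels=ts.roi_labels
    )
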