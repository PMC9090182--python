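"""Synthetic two-group BOLD cohorts with known differential connectivity.

The generator emulates the shape of an atlas-parcellated resting-state fMRI
cohort after preprocessing — per subject, a num_ROI x num_volume matrix of
mean ROI time series — with a planted ground truth that every pipeline stage
can be tested against.  Controls (NC) draw stationary Gaussian series with a
block-structured correlation matrix; patients (MCI) differ only on a planted
edge set, either by a linear correlation shift (``coupling="linear"``) or by
replacing the planted partner with a noisy quadratic function of its mate
(``coupling="quadratic"``) — an association that Pearson-style metrics miss
but MIC detects.  Temporal smoothness is injected by an AR(1) filter shared
by all ROIs, which leaves the cross-ROI correlation structure intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import SubjectTimeSeries
from .errors import InputError
from .io import Cohort

#: volumes acquired per scan and the leading volumes discarded so the
#: scanner reaches magnetization equilibrium
ACQUIRED_VOLUMES = 140
EQUILIBRATION_DISCARD = 3
DEFAULT_NUM_VOLUME = ACQUIRED_VOLUMES - EQUILIBRATION_DISCARD  # 137


def default_planted_edges(num_roi: int, n_edges: int | None = None,
                          block_size: int = 5) -> list[tuple[int, int]]:
    """Disjoint cross-block ROI pairs (baseline correlation zero).

    Defaults to 10 edges (the fixture-cohort condition) capped at what the
    ROI count can host disjointly.
    """
    defaulted = n_edges is None
    if defaulted:
        n_edges = max(1, min(10, num_roi // 2))
    edges: list[tuple[int, int]] = []
    used: set[int] = set()
    # greedy disjoint pairs across distinct blocks, nearest blocks first
    for j_off in range(block_size, num_roi):
        for i in range(num_roi - j_off):
            j = i + j_off
            if i in used or j in used or i // block_size == j // block_size:
                continue
            edges.append((i, j))
            used.update((i, j))
            if len(edges) == n_edges:
                return edges
    if defaulted and edges:
        return edges
    raise InputError(f"cannot plant {n_edges} disjoint edges among {num_roi} ROIs")


@dataclass
class CohortSpec:
    """Study conditions of one synthetic cohort.

    Defaults mirror the desk-scale fixture: 40 subjects (20 per group),
    20 ROIs, 137 volumes, 10 planted edges with a +0.5 correlation shift,
    mild temporal autocorrelation.  ``num_roi=116`` reproduces the full
    atlas width when the extra compute is acceptable.
    """

    n_per_group: int = 20
    num_roi: int = 20
    num_volume: int = DEFAULT_NUM_VOLUME
    planted_edges: list[tuple[int, int]] | None = None
    effect_delta: float = 0.5
    coupling: str = "linear"
    ar_coefficient: float = 0.3
    seed: int = 0
    block_size: int = 5
    block_rho: float = 0.1
    quad_noise: float = 0.5  # noise sd on the quadratic partner, pre-standardization

    def __post_init__(self) -> None:
        if self.coupling not in ("linear", "quadratic"):
            raise InputError("coupling must be 'linear' or 'quadratic'")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise InputError("ar_coefficient must lie in [0, 1)")
        if self.planted_edges is None:
            self.planted_edges = default_planted_edges(
                self.num_roi, block_size=self.block_size
            )
        edges = [tuple(e) for e in self.planted_edges]
        if len(set(edges)) != len(edges):
            raise InputError("planted edges must be distinct")
        for i, j in edges:
            if not (0 <= i < j < self.num_roi):
                raise InputError(f"planted edge ({i}, {j}) invalid for {self.num_roi} ROIs")
        self.planted_edges = edges


def build_group_covariance(spec: CohortSpec, group: int, repair: bool = True) -> np.ndarray:
    """Unit-diagonal correlation matrix for one group (MCI=1, NC=0).

    The baseline is block-diagonal with within-block correlation
    ``block_rho``.  In linear mode the MCI matrix shifts every planted edge
    by ``effect_delta``; quadratic coupling leaves the covariance untouched
    (the dependence is injected on the sampled series instead).  With
    ``repair`` the eigenvalues are floored at 1e-6 and the matrix is
    renormalized to unit diagonal, deterministically.
    """
    n = spec.num_roi
    cov = np.eye(n)
    for start in range(0, n, spec.block_size):
        stop = min(start + spec.block_size, n)
        cov[start:stop, start:stop] = spec.block_rho
        cov[range(start, stop), range(start, stop)] = 1.0
    if spec.coupling == "linear" and group == 1:
        for i, j in spec.planted_edges:
            v = np.clip(cov[i, j] + spec.effect_delta, -0.97, 0.97)
            cov[i, j] = cov[j, i] = v
    if repair:
        w, v = np.linalg.eigh(cov)
        if w.min() < 1e-6:
            w = np.maximum(w, 1e-6)
            cov = (v * w) @ v.T
            d = np.sqrt(np.diag(cov))
            cov = cov / np.outer(d, d)
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise InputError(
                f"covariance not repairable for effect_delta={spec.effect_delta}"
            )
    return cov


def generate_subject(spec: CohortSpec, group: int, subject_seed: int,
                     subject_id: str | None = None) -> SubjectTimeSeries:
    """One subject's ROI x volume series, reproducible from ``subject_seed``.

    Cross-sectionally correlated Gaussian innovations are passed through an
    AR(1) filter ``x_t = a x_{t-1} + sqrt(1-a^2) e_t`` (50-volume burn-in),
    preserving the target cross-ROI correlation at every lag-0 slice.  In
    quadratic mode, for MCI subjects only, each planted edge's second ROI is
    replaced by the standardized square of its mate plus Gaussian noise.
    """
    rng = np.random.default_rng(subject_seed)
    cov = build_group_covariance(spec, group)
    chol = np.linalg.cholesky(cov)
    burn = 50
    total = spec.num_volume + burn
    innov = rng.standard_normal((total, spec.num_roi)) @ chol.T
    a = spec.ar_coefficient
    series = np.empty_like(innov)
    series[0] = innov[0]
    s = np.sqrt(1.0 - a * a)
    for t in range(1, total):
        series[t] = a * series[t - 1] + s * innov[t]
    sig = series[burn:].T  # (num_roi, num_volume)

    if spec.coupling == "quadratic" and group == 1:
        for i, j in spec.planted_edges:
            x = sig[i]
            z = (x - x.mean()) / x.std()
            quad = (z * z - 1.0) / np.sqrt(2.0)
            eps = rng.standard_normal(spec.num_volume)
            sig[j] = (quad + spec.quad_noise * eps) / np.sqrt(1.0 + spec.quad_noise**2)

    sid = subject_id or f"sub{group}{subject_seed}"
    return SubjectTimeSeries(subject_id=sid, signals=sig)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """A full two-group cohort: MCI subjects first, then NC, plus ground truth."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * spec.n_per_group)
    subjects = []
    labels = []
    for idx in range(2 * spec.n_per_group):
        group = 1 if idx < spec.n_per_group else 0
        name = "MCI" if group == 1 else "NC"
        k = idx if group == 1 else idx - spec.n_per_group
        subjects.append(
            generate_subject(spec, group, int(seeds[idx]), subject_id=f"sub-{name}{k:03d}")
        )
        labels.append(group)
    return Cohort(subjects=subjects, labels=np.asarray(labels),
                  planted_edges=list(spec.planted_edges))
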