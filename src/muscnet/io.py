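"""Readers/writers, run configuration, and the end-to-end pipeline.

Time-series files are tab-separated with ROIs as rows and volumes as
columns; an optional first column carries ROI labels.  A cohort manifest is
a TSV of (subject_id, path, label) rows with labels in {MCI, NC}, preceded
by a format-version comment line.  Evaluation results are JSON validated
against the schema shipped as ``result_schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .connectivity import SubjectTimeSeries
from .dynamics import SlidingWindowConfig
from .errors import InputError, ManifestError
from .features import feature_matrix
from .mic import MicParams
from .models import (
    ALPHA_GRID,
    FusionSpec,
    alpha_grid,
    best_result,
    nested_loocv,
)

logger = logging.getLogger(__name__)

MANIFEST_TAG = "#muscnet-manifest"
MANIFEST_VERSION = "v1"
LABEL_CODES = {"MCI": 1, "NC": 0}
LABEL_NAMES = {1: "MCI", 0: "NC"}


@dataclass
class Cohort:
    """A loaded dataset: subjects, binary labels (MCI=1, NC=0), ground truth."""

    subjects: list[SubjectTimeSeries]
    labels: np.ndarray
    planted_edges: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.subjects) != self.labels.shape[0]:
            raise InputError("one label per subject required")

    @property
    def num_roi(self) -> int:
        return self.subjects[0].num_roi

    @property
    def num_volume(self) -> int:
        return self.subjects[0].num_volume


def write_time_series(ts: SubjectTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for i, row in enumerate(ts.signals):
            cells = [f"{v:.17g}" for v in row]
            if ts.roi_labels is not None:
                cells = [ts.roi_labels[i]] + cells
            fh.write("\t".join(cells) + "\n")


def read_time_series(path: str | Path, subject_id: str | None = None) -> SubjectTimeSeries:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"time-series file not found: {path}")
    rows = []
    labels = []
    has_labels = None
    with open(path) as fh:
        for ln, line in enumerate(fh):
            cells = line.rstrip("\n").split("\t")
            if not cells or cells == [""]:
                continue
            if has_labels is None:
                try:
                    float(cells[0])
                    has_labels = False
                except ValueError:
                    has_labels = True
            if has_labels:
                labels.append(cells[0])
                cells = cells[1:]
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ManifestError(f"{path}:{ln + 1}: non-numeric cell ({exc})") from exc
    if not rows:
        raise ManifestError(f"{path}: empty time-series file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ManifestError(f"{path}: ragged matrix, row lengths {sorted(lengths)}")
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem,
        signals=np.asarray(rows),
        roi_labels=labels if has_labels else None,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject TSV files plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write(f"{MANIFEST_TAG}\t{MANIFEST_VERSION}\n")
        fh.write("subject_id\tpath\tlabel\n")
        for ts, lab in zip(cohort.subjects, cohort.labels):
            fname = f"{ts.subject_id}.tsv"
            write_time_series(ts, out_dir / fname)
            fh.write(f"{ts.subject_id}\t{fname}\t{LABEL_NAMES[int(lab)]}\n")
    if cohort.planted_edges is not None:
        (out_dir / "ground_truth.json").write_text(
            json.dumps({"planted_edges": [list(e) for e in cohort.planted_edges]})
        )
    return manifest


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from its manifest; all subjects must share one shape."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    subjects: list[SubjectTimeSeries] = []
    labels: list[int] = []
    seen: set[str] = set()
    with open(manifest_path) as fh:
        first = fh.readline()
        if not first.startswith(MANIFEST_TAG):
            raise ManifestError(f"{manifest_path}: missing {MANIFEST_TAG} version line")
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["subject_id", "path", "label"]:
            raise ManifestError(f"{manifest_path}: unexpected header {header}")
        for ln, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 3:
                raise ManifestError(f"{manifest_path}:{ln + 3}: expected 3 columns")
            sid, rel, lab = cells[0], cells[1], cells[2]
            if sid in seen:
                raise ManifestError(f"duplicate subject_id {sid!r}")
            seen.add(sid)
            if lab not in LABEL_CODES:
                raise ManifestError(f"subject {sid!r}: unknown label {lab!r}")
            p = Path(rel)
            ts = read_time_series(p if p.is_absolute() else base / p, subject_id=sid)
            subjects.append(ts)
            labels.append(LABEL_CODES[lab])
    if not subjects:
        raise ManifestError(f"{manifest_path}: no subjects")
    shape = subjects[0].signals.shape
    for ts in subjects[1:]:
        if ts.signals.shape != shape:
            raise ManifestError(
                f"subject {ts.subject_id!r} has shape {ts.signals.shape}, expected {shape}"
            )
    gt = manifest_path.parent / "ground_truth.json"
    planted = None
    if gt.exists():
        planted = [tuple(e) for e in json.loads(gt.read_text())["planted_edges"]]
    return Cohort(subjects=subjects, labels=np.asarray(labels), planted_edges=planted)


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError("run configuration must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _provenance(config: dict) -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "config_hash": config_hash(config),
        "seed": (config.get("simulate") or {}).get("seed"),
        "versions": {
            "muscnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
    }


def _load_schema() -> dict:
    return json.loads(resources.files("muscnet").joinpath("result_schema.json").read_text())


def validate_result(obj: dict, schema: dict | None = None, where: str = "$") -> None:
    """Minimal structural validation against the shipped result schema.

    Supports the subset of JSON-schema keywords the schema uses: ``type``,
    ``properties``, ``required``, ``items``.  Raises :class:`InputError` on
    the first violation, naming the offending path.
    """
    schema = schema if schema is not None else _load_schema()
    t = schema.get("type")
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    if t is not None:
        if t == "null":
            if obj is not None:
                raise InputError(f"{where}: expected null")
        elif isinstance(t, list):
            ok = any(
                (obj is None and ti == "null")
                or (ti != "null" and isinstance(obj, type_map[ti])
                    and not (ti in ("number", "integer") and isinstance(obj, bool)))
                for ti in t
            )
            if not ok:
                raise InputError(f"{where}: expected one of {t}")
        else:
            py = type_map[t]
            if not isinstance(obj, py) or (t in ("number", "integer") and isinstance(obj, bool)):
                raise InputError(f"{where}: expected {t}, got {type(obj).__name__}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in obj:
                raise InputError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                validate_result(obj[key], sub, where=f"{where}.{key}")
    if t == "array" and "items" in schema:
        for i, item in enumerate(obj):
            validate_result(item, schema["items"], where=f"{where}[{i}]")


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline described by a run configuration.

    Stages: load or simulate the cohort, build per-metric connectivity
    feature matrices (static or sliding-window), run the LOOCV alpha sweep
    (or nested LOOCV) for every requested metric duet, and assemble a JSON
    report with provenance.  Configuration is validated before any compute.
    """
    cohort = _resolve_cohort(config)
    window = None
    if config.get("window_size") is not None:
        window = SlidingWindowConfig(
            window_size=int(config["window_size"]),
            window_step=int(config.get("window_step", 1)),
        )
        window.validate_for(cohort.num_volume)  # fail before any compute
    duets = [tuple(d) for d in config.get("duets", [["PCC", "PCC"]])]
    for d in duets:
        if len(d) != 2:
            raise InputError(f"duet {d!r} must name exactly two metrics")
    layout = config.get("layout", "upper_triangle")
    filter_method = config.get("filter", "Ttest")
    threshold = float(config.get("threshold", 0.05))
    mic_params = MicParams(**config.get("mic", {}))
    metrics_needed = sorted({m for d in duets for m in d})

    logger.info("building %s feature matrices for %d subjects", metrics_needed, len(cohort.subjects))
    mats = {
        m: feature_matrix(cohort.subjects, m, window=window, layout=layout, mic_params=mic_params)
        for m in metrics_needed
    }

    report: dict = {"provenance": _provenance(config), "duets": []}
    for pair in duets:
        spec = FusionSpec(
            metric_pair=pair, filter_method=filter_method, threshold=threshold,
            window=window, layout=layout,
            regularization=float(config.get("regularization", 1.0)),
        )
        if config.get("nested", False):
            res = nested_loocv(
                mats, cohort.labels, spec,
                alphas=tuple(config.get("alphas", ALPHA_GRID)),
                thresholds=tuple(config.get("thresholds", [threshold])),
            )
            entry = {"pair": list(pair), "nested": res.to_dict()}
        else:
            table = alpha_grid(mats, cohort.labels, spec,
                               alphas=tuple(config.get("alphas", ALPHA_GRID)))
            entry = {
                "pair": list(pair),
                "alpha_table": [r.to_dict() for r in table],
                "best": best_result(table).to_dict(),
            }
        report["duets"].append(entry)

    validate_result(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "evaluation.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _resolve_cohort(config: dict) -> Cohort:
    if "manifest" in config and "simulate" in config:
        raise InputError("config must give either 'manifest' or 'simulate', not both")
    if "manifest" in config:
        return read_cohort(config["manifest"])
    if "simulate" in config:
        from .synthetic import CohortSpec, generate_cohort

        return generate_cohort(CohortSpec(**config["simulate"]))
    raise InputError("config needs a 'manifest' path or a 'simulate' block")
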