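"""End-to-end orchestration: simulate, measure, analyze.

Ties the stages into one reproducible chain.  Every stochastic stage draws
its seed deterministically from the global seed plus the stage name, so one
integer reproduces the whole run.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import stats
from .morphometry import compute_all_metrics
from .orientation import LandmarkSet, apply_transform, orientation_transform
from .segmentation import expand_sphere, interior_box, segment_roi
from .synthetic import CohortSpec, PhantomSpec, WholeBoneSpec, generate_whole_bone, simulate_cohort
from .volume import VoxelVolume, write_stack

__all__ = ["PipelineConfig", "derive_seed", "measure_specimen",
           "simulate_to_dir", "measure_batch", "analyze_table"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """All stage parameters plus the single global seed."""

    seed: int = 0
    n_directions: int = 512
    line_spacing: float = 2.0
    tbn_method: str = "plate_model"
    alpha: float = 0.05
    k_folds: int = 10
    candidate_degrees: tuple[int, ...] = (1, 2, 3, 4)
    adjustment: str = "none"
    pca_scale: bool = False
    correlation_mode: str = "pearson"
    mass_coefficients: tuple[float, float] | None = None
    interpolation: str = "nearest"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("candidate_degrees", "mass_coefficients"):
            if tup in raw and raw[tup] is not None:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


def measure_specimen(gray: VoxelVolume, labels: VoxelVolume,
                     landmarks: LandmarkSet | pd.DataFrame,
                     config: PipelineConfig | None = None) -> dict[str, Any]:
    """Orientation → interior box → spherical ROI → Otsu + purify →
    morphometry for one specimen; returns one metrics row with provenance."""
    config = config or PipelineConfig()
    if isinstance(landmarks, pd.DataFrame):
        landmarks = LandmarkSet.from_table(landmarks)
    t = orientation_transform(landmarks)
    oriented = apply_transform(gray, t, interpolation=config.interpolation)
    oriented_labels = apply_transform(labels, t, interpolation="nearest")
    pts = t.apply(landmarks.points()) - oriented.origin
    head_center = 0.5 * (pts[2] + pts[3])  # midpoint of the lateral contacts
    cortical = oriented_labels.values == 2
    box = interior_box(cortical, head_center)
    roi = expand_sphere(box, cortical)
    seg = segment_roi(oriented, roi)
    metrics = compute_all_metrics(
        seg, n_directions=config.n_directions, line_spacing=config.line_spacing,
        seed=config.stage_seed("mil"), tbn_method=config.tbn_method)
    row = metrics.as_row()
    row.update({"roi_radius_vox": roi.radius,
                "roi_center_x": roi.center[0], "roi_center_y": roi.center[1],
                "roi_center_z": roi.center[2],
                "otsu_threshold": seg.otsu_threshold})
    return row


def simulate_to_dir(out_dir: str | Path, kind: str = "cohort",
                    spec: CohortSpec | WholeBoneSpec | PhantomSpec | None = None,
                    seed: int = 0, force: bool = False) -> Path:
    """Write simulated fixtures plus a manifest recording the configuration.

    kind = 'cohort' writes cohort.csv; kind = 'whole_bone' writes grayscale
    and label TIFF stacks with a landmark CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.json"
    if manifest.exists() and not force:
        raise FileExistsError(f"{manifest} exists; pass force=True to overwrite")
    if kind == "cohort":
        spec = spec or CohortSpec(seed=seed)
        table = simulate_cohort(spec)
        table.to_csv(out_dir / "cohort.csv", index=False)
        written = ["cohort.csv"]
    elif kind == "whole_bone":
        spec = spec or WholeBoneSpec(seed=seed)
        gray, labels, landmarks = generate_whole_bone(spec)
        write_stack(gray, out_dir / "grayscale.tif")
        write_stack(labels, out_dir / "labels.tif")
        landmarks.to_csv(out_dir / "landmarks.csv", index=False)
        written = ["grayscale.tif", "labels.tif", "landmarks.csv"]
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    payload = {"kind": kind, "seed": seed, "files": written,
               "spec": json.loads(json.dumps(asdict(spec), default=_jsonable))}
    manifest.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out_dir


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def measure_batch(specimens: list[dict[str, Any]],
                  config: PipelineConfig | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Run :func:`measure_specimen` over a batch.

    Each entry needs keys specimen_id, gray, labels, landmarks (plus any
    metadata columns to carry through).  Per-specimen failures are recorded
    and skipped; the error list is returned alongside the table.
    """
    rows, errors = [], []
    for item in specimens:
        try:
            row = measure_specimen(item["gray"], item["labels"], item["landmarks"], config)
            row.update({k: v for k, v in item.items()
                        if k not in ("gray", "labels", "landmarks")})
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 — batch isolation is the point
            errors.append({"specimen_id": item.get("specimen_id"), "error": str(exc)})
    return pd.DataFrame(rows), errors


def analyze_table(table: pd.DataFrame, config: PipelineConfig | None = None) -> dict[str, Any]:
    """Statistics stage with config-derived seeding."""
    config = config or PipelineConfig()
    return stats.run_cohort_analysis(
        table, alpha=config.alpha, adjustment=config.adjustment,
        k=config.k_folds, seed=config.stage_seed("regression"),
        candidate_degrees=config.candidate_degrees, pca_scale=config.pca_scale,
        correlation_mode=config.correlation_mode)
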