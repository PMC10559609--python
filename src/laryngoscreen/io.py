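"""Frames, labelme-style polygon annotations, dataset manifests and video I/O.

The dataset conventions mirror how laryngoscopy screening datasets are
assembled in practice: frames are extracted from endoscopy video, tagged
with an imaging modality (white-light WLI or narrow-band NBI), capped at
ten frames per patient to avoid over-representing any one examination, and
split into train / verification / test sets that are disjoint at the
patient level so no patient leaks across splits.  Cancer lesions are
delineated as polygons in labelme-dialect JSON and rasterized to binary
masks for segmentation training.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from . import avi as _avi

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "Frame",
    "PolygonShape",
    "AnnotationFile",
    "ManifestRecord",
    "DatasetManifest",
    "Violation",
    "read_annotation",
    "write_annotation",
    "rasterize_annotation",
    "validate_manifest",
    "read_image",
    "write_image",
    "read_video_frames",
    "MAX_FRAMES_PER_PATIENT",
    "PATHOLOGY_LABELS",
    "SPLITS",
]

MAX_FRAMES_PER_PATIENT = 10
PATHOLOGY_LABELS = ("cancer", "benign", "normal")
SPLITS = ("train", "verification", "test")


class Modality(str, enum.Enum):
    """Endoscopic imaging modality."""

    WLI = "WLI"
    NBI = "NBI"


@dataclass
class Frame:
    """One endoscopy frame with its provenance and optional truth mask."""

    image: np.ndarray  # (H, W, 3) uint8
    modality: Modality
    patient_id: str
    frame_index: int = 0
    mask: Optional[np.ndarray] = None  # (H, W) {0,1}

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("Frame.image must be an (H, W, 3) RGB raster")
        if not isinstance(self.modality, Modality):
            self.modality = Modality(self.modality)
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image "
                    f"shape {self.image.shape[:2]}"
                )


@dataclass
class PolygonShape:
    label: str
    points: np.ndarray  # (V, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("polygon points must be an (V, 2) array of (x, y)")
        if len(self.points) < 3:
            raise ValueError(f"polygon '{self.label}' has < 3 vertices")
        if not np.all(np.isfinite(self.points)) or np.any(self.points < 0):
            raise ValueError(f"polygon '{self.label}' has non-finite or negative vertices")


@dataclass
class AnnotationFile:
    """Labelme-dialect polygon annotation for one image."""

    image_path: str
    image_height: int
    image_width: int
    shapes: list[PolygonShape] = field(default_factory=list)


def read_annotation(path) -> AnnotationFile:
    """Parse a labelme-dialect JSON annotation file.

    Unknown keys are ignored; shape order is preserved.  Raises ``ValueError``
    (naming the path) on malformed JSON or a polygon with fewer than three
    vertices.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed annotation JSON in {path}: {exc}") from exc
    try:
        shapes = [
            PolygonShape(label=s.get("label", ""), points=np.asarray(s["points"], float))
            for s in doc.get("shapes", [])
        ]
    except ValueError as exc:
        raise ValueError(f"invalid polygon in {path}: {exc}") from exc
    return AnnotationFile(
        image_path=doc.get("imagePath", ""),
        image_height=int(doc.get("imageHeight", 0)),
        image_width=int(doc.get("imageWidth", 0)),
        shapes=shapes,
    )


def write_annotation(ann: AnnotationFile, path) -> None:
    """Write an annotation as labelme-dialect JSON."""
    doc = {
        "version": "5.0.0",
        "imagePath": ann.image_path,
        "imageHeight": int(ann.image_height),
        "imageWidth": int(ann.image_width),
        "imageData": None,
        "shapes": [
            {
                "label": s.label,
                "points": np.asarray(s.points, float).tolist(),
                "shape_type": "polygon",
                "group_id": None,
                "flags": {},
            }
            for s in ann.shapes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def polygon_mask(points: np.ndarray, height: int, width: int) -> np.ndarray:
    """Rasterize one polygon: pixel (r, c) is set iff its center (x=c, y=r)
    lies inside the polygon, boundary included."""
    poly = shapely.Polygon(np.asarray(points, float))
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    if poly.area == 0:
        logger.warning("degenerate zero-area polygon skipped")
        return np.zeros((height, width), dtype=np.uint8)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, math.floor(minx))
    c1 = min(width - 1, math.ceil(maxx))
    r0 = max(0, math.floor(miny))
    r1 = min(height - 1, math.ceil(maxy))
    out = np.zeros((height, width), dtype=np.uint8)
    if c1 < c0 or r1 < r0:
        return out  # entirely outside the raster: clipped, not an error
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.intersects_xy(poly, cols.ravel().astype(float), rows.ravel().astype(float))
    out[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rows.shape)
    return out


def rasterize_annotation(
    ann: AnnotationFile,
    height: int,
    width: int,
    cancer_labels: Sequence[str] = ("cancer",),
) -> np.ndarray:
    """Union of all cancer-labeled polygons as a {0,1} uint8 raster.

    Containment is decided at pixel centers (x = column index, y = row
    index); points exactly on a polygon edge count as inside.  Vertices
    outside the raster are clipped.
    """
    if height <= 0 or width <= 0:
        raise ValueError("raster dimensions must be positive")
    mask = np.zeros((height, width), dtype=np.uint8)
    for shape in ann.shapes:
        if shape.label in cancer_labels:
            mask |= polygon_mask(shape.points, height, width)
    return mask


@dataclass
class ManifestRecord:
    patient_id: str
    frame_path: str
    annotation_path: Optional[str]
    modality: Modality
    label: str  # pathology: cancer / benign / normal
    split: str  # train / verification / test
    excluded: bool = False  # quality-control exclusion flag (human review)


@dataclass
class DatasetManifest:
    """Patient-level dataset manifest (one row per frame)."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str | None = None, modality: Modality | None = None,
               include_excluded: bool = False) -> "DatasetManifest":
        recs = [
            r
            for r in self.records
            if (split is None or r.split == split)
            and (modality is None or r.modality == modality)
            and (include_excluded or not r.excluded)
        ]
        return DatasetManifest(recs)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "frame_path": [r.frame_path for r in self.records],
                "annotation_path": [r.annotation_path or "" for r in self.records],
                "modality": [r.modality.value for r in self.records],
                "label": [r.label for r in self.records],
                "split": [r.split for r in self.records],
                "excluded": [int(r.excluded) for r in self.records],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = [
            ManifestRecord(
                patient_id=row["patient_id"],
                frame_path=row["frame_path"],
                annotation_path=row["annotation_path"] or None,
                modality=Modality(row["modality"]),
                label=row["label"],
                split=row["split"],
                excluded=bool(int(row.get("excluded", "0") or 0)),
            )
            for _, row in df.iterrows()
        ]
        return cls(records)


@dataclass
class Violation:
    code: str
    patient_id: str
    message: str


def validate_manifest(manifest: DatasetManifest) -> list[Violation]:
    """Check the dataset-construction rules; violations are data, not errors.

    Rules: every patient lives in exactly one split (no leakage between
    train / verification / test), at most ten frames per patient, and each
    cancer-labeled training frame carries a lesion annotation.
    """
    violations: list[Violation] = []
    splits_by_patient: dict[str, set[str]] = {}
    frames_by_patient: dict[str, int] = {}
    for rec in manifest:
        if rec.label not in PATHOLOGY_LABELS:
            violations.append(
                Violation("bad_label", rec.patient_id,
                          f"unknown pathology label {rec.label!r} for {rec.frame_path}")
            )
        if rec.split not in SPLITS:
            violations.append(
                Violation("bad_split", rec.patient_id,
                          f"unknown split {rec.split!r} for {rec.frame_path}")
            )
        splits_by_patient.setdefault(rec.patient_id, set()).add(rec.split)
        frames_by_patient[rec.patient_id] = frames_by_patient.get(rec.patient_id, 0) + 1
        if rec.label == "cancer" and rec.split == "train" and not rec.annotation_path:
            violations.append(
                Violation("missing_annotation", rec.patient_id,
                          f"cancer training frame without annotation: {rec.frame_path}")
            )
    for pid, splits in splits_by_patient.items():
        if len(splits) > 1:
            violations.append(
                Violation("split_leakage", pid,
                          f"patient appears in multiple splits: {sorted(splits)}")
            )
    for pid, n in frames_by_patient.items():
        if n > MAX_FRAMES_PER_PATIENT:
            violations.append(
                Violation("frame_cap_exceeded", pid,
                          f"{n} frames exceed the {MAX_FRAMES_PER_PATIENT}-frame cap")
            )
    return violations


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.asarray(img[..., :3], dtype=np.uint8)


def write_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_video_frames(
    path,
    modality: Modality = Modality.WLI,
    patient_id: str = "",
    fps: Optional[float] = None,
):
    """Read an endoscopy video into ordered :class:`Frame` objects.

    Uncompressed AVI is read natively; other containers (MP4, compressed
    AVI) are delegated to imageio, which requires an ffmpeg plugin.  Returns
    ``(frames, fps)`` with ``frame_index`` running 0..N−1.  ``fps`` given
    explicitly overrides (or supplies missing) container metadata.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    images: list[np.ndarray]
    if path.suffix.lower() == ".avi":
        try:
            images, meta_fps = _avi.read_avi(path)
        except IOError:
            if fps is None:
                raise
            images, meta_fps = None, None  # fall through to imageio below
        if images is not None:
            rate = fps if fps is not None else meta_fps
            frames = [
                Frame(image=img, modality=modality, patient_id=patient_id, frame_index=i)
                for i, img in enumerate(images)
            ]
            return frames, float(rate)
    try:
        import imageio.v3 as iio

        images = [np.asarray(f[..., :3], np.uint8) for f in iio.imiter(path)]
        meta = iio.immeta(path)
        meta_fps = meta.get("fps")
    except Exception as exc:
        raise IOError(f"could not read video container {path}: {exc}") from exc
    if fps is None and not meta_fps:
        raise IOError(
            f"no frame-rate metadata in {path}; pass fps=... explicitly"
        )
    frames = [
        Frame(image=img, modality=modality, patient_id=patient_id, frame_index=i)
        for i, img in enumerate(images)
    ]
    return frames, float(fps if fps is not None else meta_fps)
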