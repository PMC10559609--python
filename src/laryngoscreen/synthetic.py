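"""Seed-controlled synthetic laryngoscopy data.

Clinical endoscopy datasets are private, so every pipeline stage is
exercised on generated data that reproduces the *statistical structure*
the pipeline relies on, not the photorealism of mucosa:

* frames carry a modality tag with modality-dependent appearance — WLI
  frames use a broad pink/red mucosal palette, NBI frames a darker
  green/brown palette overlaid with curvilinear vessel-like texture;
* cancer frames contain one irregular star-convex lesion whose mask area
  falls in a configurable range; both classes may carry small distractor
  blobs (specular reflections, secretions) that are *not* part of the
  truth mask;
* videos last 8–25 s per lesion with the lesion visible in one contiguous,
  jittered run of frames — mirroring clip videos that each contain a
  single lesion;
* everything is a pure function of (config, seed, call arguments).

The lesion/distractor area ranges control class separability: with
lesions much larger than distractors, thresholding the largest connected
component of the true mask classifies frames perfectly, which is the
fixture that threshold-selection tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

from . import avi as _avi
from .io import (
    AnnotationFile,
    DatasetManifest,
    Frame,
    ManifestRecord,
    Modality,
    PolygonShape,
    write_annotation,
    write_image,
)

__all__ = ["SynthConfig", "generate_frame", "generate_dataset", "generate_video",
           "trace_mask_to_polygons"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults describe 128×128 frames with one conspicuous lesion per cancer
    frame (mask area 600–3000 px, i.e. 4–18% of the frame — scaled from
    lesion sizes that dominate a 512×512 endoscopy frame) and small
    distractors well below the area decision threshold. Videos run at
    25 fps for 8–25 s per lesion, the clip lengths used for video-level
    screening, with the lesion visible in ~60% of frames.
    """

    seed: int = 0
    image_size: tuple[int, int] = (128, 128)  # (H, W)
    lesion_probability: float = 0.5
    lesion_area_range: tuple[int, int] = (600, 3000)  # px at image_size
    distractor_area_range: tuple[int, int] = (8, 60)
    distractor_count_range: tuple[int, int] = (0, 2)
    modality_mix: float = 0.5  # fraction WLI
    noise_sd: float = 6.0  # 8-bit intensity units
    video_fps: float = 25.0
    video_duration_range: tuple[float, float] = (8.0, 25.0)  # s per lesion clip
    lesion_persistence: float = 0.6  # fraction of video frames showing the lesion

    def __post_init__(self) -> None:
        for name in ("lesion_area_range", "distractor_area_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive with min <= max")
        if not 0 <= self.lesion_probability <= 1:
            raise ValueError("lesion_probability must be in [0, 1]")
        if not 0 <= self.modality_mix <= 1:
            raise ValueError("modality_mix must be in [0, 1]")
        h, w = self.image_size
        if self.lesion_area_range[1] > 0.5 * h * w:
            raise ValueError(
                f"lesion_area_range {self.lesion_area_range} infeasible for "
                f"image_size {self.image_size}"
            )
        lo, hi = self.video_duration_range
        if lo <= 0 or hi < lo:
            raise ValueError("video_duration_range must be positive with min <= max")
        if not 0 < self.lesion_persistence <= 1:
            raise ValueError("lesion_persistence must be in (0, 1]")


# ----------------------------------------------------------------- textures

def _smooth_noise(rng, shape, sigma, lo, hi):
    x = gaussian_filter(rng.standard_normal(shape), sigma)
    x = (x - x.min()) / (np.ptp(x) + 1e-12)
    return lo + (hi - lo) * x


def _background(rng: np.random.Generator, size, modality: Modality) -> np.ndarray:
    h, w = size
    img = np.zeros((h, w, 3), dtype=np.float32)
    if modality is Modality.WLI:
        # broad pink/red mucosa under white light
        base = np.array([205.0, 140.0, 140.0])
        amp = np.array([35.0, 30.0, 30.0])
    else:
        # NBI: darker green/brown cast
        base = np.array([105.0, 125.0, 95.0])
        amp = np.array([30.0, 30.0, 25.0])
    for c in range(3):
        img[..., c] = base[c] + amp[c] * (_smooth_noise(rng, (h, w), sigma=h / 10, lo=-1, hi=1))
    # radial vignette, as endoscope optics produce
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot((yy - h / 2) / h, (xx - w / 2) / w)
    img *= (1.0 - 0.55 * r**2)[..., None]
    if modality is Modality.NBI:
        # curvilinear vessel-like dark strokes
        vessels = np.zeros((h, w), dtype=np.float32)
        n_vessels = rng.integers(6, 12)
        for _ in range(n_vessels):
            y = rng.uniform(0, h)
            x = rng.uniform(0, w)
            ang = rng.uniform(0, 2 * np.pi)
            step = max(1.0, h / 64)
            for _ in range(int(rng.integers(h // 4, h))):
                iy, ix = int(y), int(x)
                if 0 <= iy < h and 0 <= ix < w:
                    vessels[iy, ix] = 1.0
                ang += rng.normal(0, 0.3)
                y += step * np.sin(ang)
                x += step * np.cos(ang)
        vessels = gaussian_filter(vessels, 0.8)
        vessels /= vessels.max() + 1e-12
        img *= (1.0 - 0.5 * vessels)[..., None]
    return img


def _star_polygon(rng: np.random.Generator, center, mean_radius, irregularity=0.35,
                  n_vertices=24) -> np.ndarray:
    """Star-convex polygon: radial perturbation of an ellipse around center.

    Irregular like carcinoma margins yet exactly traceable back to a
    polygon annotation. Returns (V, 2) array of (x, y) vertices.
    """
    cy, cx = center
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ecc = rng.uniform(0.7, 1.3)
    raw = rng.normal(0, 1, n_vertices)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    smooth = np.convolve(np.tile(raw, 3), kernel / kernel.sum(), "same")[
        n_vertices : 2 * n_vertices
    ]
    radii = mean_radius * (1 + irregularity * smooth / (np.abs(smooth).max() + 1e-12))
    radii = np.clip(radii, 0.3 * mean_radius, 1.8 * mean_radius)
    xs = cx + radii * ecc * np.cos(theta)
    ys = cy + radii / ecc * np.sin(theta)
    return np.stack([xs, ys], axis=1)


def _rasterize_points(points, h, w):
    from .io import polygon_mask

    return polygon_mask(points, h, w)


def _blob_mask(rng, size, area_range, margin=0.1):
    """Star-convex blob whose rasterized area lands inside area_range."""
    h, w = size
    target = float(rng.uniform(*area_range))
    mean_r = np.sqrt(target / np.pi)
    cy = rng.uniform(margin * h + mean_r, (1 - margin) * h - mean_r) if h > 2 * (margin * h + mean_r) else h / 2
    cx = rng.uniform(margin * w + mean_r, (1 - margin) * w - mean_r) if w > 2 * (margin * w + mean_r) else w / 2
    pts = _star_polygon(rng, (cy, cx), mean_r)
    for _ in range(8):
        mask = _rasterize_points(pts, h, w)
        area = int(mask.sum())
        if area_range[0] <= area <= area_range[1]:
            return mask, pts
        if area == 0:
            scale = 2.0
        else:
            scale = np.sqrt(target / area)
        pts = np.stack([cx + (pts[:, 0] - cx) * scale, cy + (pts[:, 1] - cy) * scale], axis=1)
        pts = np.clip(pts, 0, [w - 1, h - 1])
    return mask, pts  # best effort after clipping; callers assert in tests


def _apply_blob(img, mask, modality, rng, kind="lesion"):
    h, w = mask.shape
    soft = gaussian_filter(mask.astype(np.float32), 1.0)
    m = soft.max()
    if m > 0:
        soft = soft / m
    if kind == "lesion":
        if modality is Modality.WLI:
            color = np.array([185.0, 75.0, 70.0], dtype=np.float32)
        else:
            color = np.array([80.0, 52.0, 40.0], dtype=np.float32)
        texture = _smooth_noise(rng, (h, w), sigma=2.0, lo=0.75, hi=1.25).astype(np.float32)
    else:
        color = np.array([235.0, 232.0, 225.0], dtype=np.float32)
        texture = np.ones((h, w), dtype=np.float32)
    blend = (0.85 * soft)[..., None]
    overlay = color[None, None, :] * texture[..., None]
    return img * (1 - blend) + overlay * blend


def generate_frame(
    cfg: SynthConfig,
    cancer: bool,
    modality: Modality = Modality.WLI,
    rng: Optional[np.random.Generator] = None,
    patient_id: str = "synthetic",
    frame_index: int = 0,
) -> Frame:
    """Generate one frame with its ground-truth mask.

    The mask marks exactly the cancer lesion (all-zero for non-cancer
    frames); distractor blobs are painted into the image but never enter
    the mask.  Deterministic given (cfg, rng state, arguments).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    modality = Modality(modality)
    h, w = cfg.image_size
    img = _background(rng, cfg.image_size, modality)

    n_distract = int(rng.integers(cfg.distractor_count_range[0],
                                  cfg.distractor_count_range[1] + 1))
    for _ in range(n_distract):
        dmask, _ = _blob_mask(rng, cfg.image_size, cfg.distractor_area_range, margin=0.05)
        img = _apply_blob(img, dmask, modality, rng, kind="distractor")

    mask = np.zeros((h, w), dtype=np.uint8)
    if cancer:
        mask, _ = _blob_mask(rng, cfg.image_size, cfg.lesion_area_range)
        img = _apply_blob(img, mask, modality, rng, kind="lesion")

    img = img + rng.normal(0, cfg.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return Frame(image=img, modality=modality, patient_id=patient_id,
                 frame_index=frame_index, mask=mask)


def trace_mask_to_polygons(mask: np.ndarray, label: str = "cancer",
                           step: int = 3) -> list[PolygonShape]:
    """Trace a binary mask's component contours to labelme polygons.

    Contours come from marching squares at the 0.5 level; vertices are
    subsampled every ``step`` points to keep annotation files small.
    """
    shapes = []
    padded = np.pad(np.asarray(mask, float), 1)
    for contour in measure.find_contours(padded, 0.5):
        contour = contour - 1.0  # undo padding
        pts = contour[::step]
        if len(pts) < 3:
            continue
        xy = np.stack([pts[:, 1], pts[:, 0]], axis=1)  # (row, col) -> (x, y)
        xy = np.clip(xy, 0, [mask.shape[1] - 1, mask.shape[0] - 1])
        shapes.append(PolygonShape(label=label, points=xy))
    return shapes


def generate_dataset(
    cfg: SynthConfig,
    out_dir,
    n_patients: int,
    frames_per_patient: int = 5,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    image_format: str = "png",
) -> DatasetManifest:
    """Write a patient-structured synthetic dataset to disk.

    Per patient: one pathology (cancer with probability
    ``lesion_probability``, otherwise benign or normal), up to ten frames,
    labelme polygon annotations traced from the lesion contours of cancer
    frames, and a manifest CSV with patient-disjoint splits.
    """
    if frames_per_patient > 10:
        raise ValueError("frames_per_patient must be <= 10 (per-patient frame cap)")
    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # patient-disjoint splits in the requested proportions
    n_train = int(round(split_fractions[0] * n_patients))
    n_ver = int(round(split_fractions[1] * n_patients))
    split_of = ["train"] * n_train + ["verification"] * n_ver
    split_of += ["test"] * (n_patients - len(split_of))
    rng.shuffle(split_of)

    records: list[ManifestRecord] = []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        cancer = bool(rng.random() < cfg.lesion_probability)
        label = "cancer" if cancer else ("benign" if rng.random() < 0.5 else "normal")
        for k in range(frames_per_patient):
            modality = Modality.WLI if rng.random() < cfg.modality_mix else Modality.NBI
            frame = generate_frame(cfg, cancer, modality, rng,
                                   patient_id=pid, frame_index=k)
            frame_path = out_dir / "frames" / f"{pid}_{k:02d}.{image_format}"
            write_image(frame_path, frame.image)
            ann_path = None
            if cancer:
                shapes = trace_mask_to_polygons(frame.mask)
                ann = AnnotationFile(
                    image_path=frame_path.name,
                    image_height=cfg.image_size[0],
                    image_width=cfg.image_size[1],
                    shapes=shapes,
                )
                ann_path = out_dir / "annotations" / f"{pid}_{k:02d}.json"
                write_annotation(ann, ann_path)
            records.append(
                ManifestRecord(
                    patient_id=pid,
                    frame_path=str(frame_path.relative_to(out_dir)),
                    annotation_path=str(ann_path.relative_to(out_dir)) if ann_path else None,
                    modality=modality,
                    label=label,
                    split=split_of[p],
                )
            )
    manifest = DatasetManifest(records)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def generate_video(
    cfg: SynthConfig,
    cancer: bool,
    path=None,
    rng: Optional[np.random.Generator] = None,
):
    """Generate one endoscopy clip with per-frame truth labels.

    Duration is drawn from ``video_duration_range``; a cancer clip shows
    the lesion in one contiguous run of ``round(lesion_persistence × N)``
    frames, jittered in position and scale frame to frame.  If ``path``
    is given, an uncompressed AVI is written there.

    Returns ``(frames, truth_labels, fps)`` where ``truth_labels[i]`` is
    True iff the lesion is visible in frame i.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    duration = float(rng.uniform(*cfg.video_duration_range))
    n_frames = max(1, int(round(duration * cfg.video_fps)))
    modality = Modality.WLI if rng.random() < cfg.modality_mix else Modality.NBI

    base = _background(rng, cfg.image_size, modality)
    truth = np.zeros(n_frames, dtype=bool)
    lesion_pts = None
    if cancer:
        run = max(1, int(round(cfg.lesion_persistence * n_frames)))
        start = int(rng.integers(0, n_frames - run + 1))
        truth[start : start + run] = True
        _, lesion_pts = _blob_mask(rng, cfg.image_size, cfg.lesion_area_range)

    frames = []
    labels = []
    drift = np.zeros(2)
    scale = 1.0
    for i in range(n_frames):
        img = base.copy()
        if truth[i]:
            drift += rng.normal(0, 0.6, 2)
            drift = np.clip(drift, -0.08 * w, 0.08 * w)
            scale = float(np.clip(scale * (1 + rng.normal(0, 0.01)), 0.9, 1.1))
            c = lesion_pts.mean(axis=0)
            pts = (lesion_pts - c) * scale + c + drift
            pts = np.clip(pts, 0, [w - 1, h - 1])
            fmask = _rasterize_points(pts, h, w)
            img = _apply_blob(img, fmask, modality, rng, kind="lesion")
        img = np.clip(img + rng.normal(0, cfg.noise_sd, img.shape), 0, 255).astype(np.uint8)
        frames.append(img)
        labels.append(bool(truth[i]))

    if path is not None:
        _avi.write_avi(path, frames, cfg.video_fps)
    return frames, labels, float(cfg.video_fps)
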