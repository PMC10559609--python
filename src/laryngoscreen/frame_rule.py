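"""Frame-level cancer call from a predicted segmentation mask.

The decision layer mirrors clinical screening practice: the predicted
mask is cleaned with morphological closing then opening (filling voids and
removing speckle), connected components are labelled, and the frame is
called *cancer* iff the largest component's area strictly exceeds an area
threshold — 32×32 = 1024 px at the 512×512 working resolution by default.
The threshold itself is selected from the candidate grid
8×8, 16×16, 32×32, 64×64, 128×128, 256×256 by exhaustive evaluation on a
verification split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology

__all__ = [
    "FrameDecision",
    "AreaThresholdGrid",
    "DEFAULT_AREA_THRESHOLD",
    "WORKING_RESOLUTION",
    "clean_mask",
    "classify_frame",
    "scaled_area_threshold",
    "select_area_threshold",
]

WORKING_RESOLUTION = (512, 512)
DEFAULT_AREA_THRESHOLD = 32 * 32  # px at the 512x512 working resolution


@dataclass
class FrameDecision:
    is_cancer: bool
    largest_component_area: int  # px, post-morphology
    component_count: int
    score: float  # continuous ROC score (largest-component area)


@dataclass(frozen=True)
class AreaThresholdGrid:
    """Candidate area thresholds: squares of side 8..256 px."""

    candidate_areas: tuple[int, ...] = (64, 256, 1024, 4096, 16384, 65536)
    metric: str = "accuracy"

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.candidate_areas, self.candidate_areas[1:])):
            raise ValueError("candidate areas must be strictly increasing")


def clean_mask(mask: np.ndarray, structuring_element_size: int = 5) -> np.ndarray:
    """Morphological closing then opening with one square structuring element.

    Closing (dilation then erosion) fills interior voids; opening (erosion
    then dilation) removes isolated speckle.  Output is binary with the
    input's shape.
    """
    mask = np.asarray(mask)
    se = structuring_element_size
    if se < 1:
        raise ValueError("structuring element size must be >= 1")
    if se > min(mask.shape):
        raise ValueError(
            f"structuring element {se} exceeds image extent {mask.shape}"
        )
    footprint = np.ones((se, se), dtype=bool)
    m = mask.astype(bool)
    m = morphology.closing(m, footprint)
    m = morphology.opening(m, footprint)
    return m.astype(np.uint8)


def classify_frame(
    mask: np.ndarray,
    area_threshold: float = DEFAULT_AREA_THRESHOLD,
    connectivity: int = 2,
    mode: str = "largest",
) -> FrameDecision:
    """Area-threshold cancer call on a (cleaned) binary mask.

    Components are labelled with 8-connectivity by default
    (``connectivity=2``; diagonal-linked tumour pixels form one region).
    ``mode="largest"`` uses the largest single component's area (regions
    are anatomically connected); ``mode="sum"`` uses the summed area of
    all components.  The call is *cancer* iff the area strictly exceeds
    ``area_threshold`` ("exceeding" is a strict inequality: a component of
    exactly the threshold area is non-cancer).
    """
    if mode not in ("largest", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = measure.label(np.asarray(mask).astype(bool), connectivity=connectivity)
    n_components = int(labels.max())
    if n_components == 0:
        area = 0
    else:
        counts = np.bincount(labels.ravel())[1:]
        area = int(counts.max()) if mode == "largest" else int(counts.sum())
    return FrameDecision(
        is_cancer=bool(area > area_threshold),
        largest_component_area=area if mode == "largest" else
        (int(np.bincount(labels.ravel())[1:].max()) if n_components else 0),
        component_count=n_components,
        score=float(area),
    )


def scaled_area_threshold(
    mask_shape: tuple[int, int],
    base_area: float = DEFAULT_AREA_THRESHOLD,
    working_resolution: tuple[int, int] = WORKING_RESOLUTION,
) -> float:
    """Area threshold equivalent at a non-working resolution.

    The 32×32 rule is defined at 512×512; a mask of another size uses the
    area scaled by the pixel-count ratio, so the same physical fraction of
    the frame triggers the call.
    """
    h, w = mask_shape
    wh, ww = working_resolution
    return base_area * (h * w) / (wh * ww)


def select_area_threshold(
    areas,
    truth_labels,
    grid: AreaThresholdGrid = AreaThresholdGrid(),
):
    """Pick the area threshold by exhaustive grid evaluation.

    Parameters
    ----------
    areas : sequence of float
        Per-frame largest-component areas (post-morphology) on the
        verification split.
    truth_labels : sequence of bool
        Per-frame pathology truth (True = cancer).
    grid : AreaThresholdGrid
        Candidate thresholds and selection metric (accuracy by default).

    Returns
    -------
    selected : int
        Best candidate; ties break toward the smaller threshold (favouring
        sensitivity, the screening-relevant direction).
    table : pandas.DataFrame
        Full metric-vs-threshold table (columns: threshold, accuracy,
        sensitivity, specificity, n_positive_calls).
    """
    areas = np.asarray(areas, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if areas.shape != truth.shape:
        raise ValueError("areas and truth_labels must align")
    if truth.all() or not truth.any():
        raise ValueError("verification set must contain both classes")
    if grid.metric != "accuracy":
        raise ValueError(f"unsupported selection metric {grid.metric!r}")
    rows = []
    for thr in grid.candidate_areas:
        calls = areas > thr
        rows.append(
            {
                "threshold": thr,
                "accuracy": float(np.mean(calls == truth)),
                "sensitivity": float(np.mean(calls[truth])),
                "specificity": float(np.mean(~calls[~truth])),
                "n_positive_calls": int(calls.sum()),
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.loc[table["accuracy"].idxmax(), "threshold"])  # idxmax -> first max
    return best, table
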