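"""Video-level diagnosis from a stream of per-frame cancer calls.

A clip is diagnosed as cancer iff some run of *consecutive* cancer frames
lasts strictly longer than a duration threshold (2 s by default, selected
from the candidate grid 0.5, 1, 1.5, 2, 2.5, 3 s).  Run duration is
``run_length / fps``; a single negative frame breaks a run unless an
explicit gap tolerance is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .frame_rule import FrameDecision, classify_frame, clean_mask, scaled_area_threshold
from .io import Frame

__all__ = [
    "VideoDiagnosis",
    "DurationThresholdGrid",
    "DEFAULT_DURATION_THRESHOLD",
    "longest_run",
    "diagnose_video",
    "stream_diagnose",
    "select_duration_threshold",
]

DEFAULT_DURATION_THRESHOLD = 2.0  # seconds


@dataclass
class VideoDiagnosis:
    is_cancer: bool
    longest_run_frames: int
    longest_run_seconds: float
    fps: float
    n_frames: int


@dataclass(frozen=True)
class DurationThresholdGrid:
    candidates: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    metric: str = "accuracy"

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.candidates, self.candidates[1:])):
            raise ValueError("duration candidates must be strictly increasing")


def longest_run(values: Sequence[bool], gap_tolerance: int = 0) -> int:
    """Length of the longest run of True values.

    With ``gap_tolerance = g > 0``, runs separated by at most g consecutive
    False frames are merged (the gap frames do not count toward the run
    length).  The default g = 0 is the strict consecutive rule.
    """
    vals = np.asarray(list(values), dtype=bool)
    if gap_tolerance == 0:
        best = cur = 0
        for v in vals:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        return best
    best = 0
    n = len(vals)
    i = 0
    while i < n:
        if not vals[i]:
            i += 1
            continue
        count = 0
        gap = 0
        j = i
        while j < n:
            if vals[j]:
                count += 1
                gap = 0
            else:
                gap += 1
                if gap > gap_tolerance:
                    break
            j += 1
        best = max(best, count)
        i += 1
    return best


def diagnose_video(
    frame_decisions: Sequence[bool],
    fps: float,
    duration_threshold: float = DEFAULT_DURATION_THRESHOLD,
    gap_tolerance: int = 0,
) -> VideoDiagnosis:
    """Apply the consecutive-duration rule to an ordered decision sequence.

    ``is_cancer`` iff the longest run of consecutive positive frames spans
    strictly more than ``duration_threshold`` seconds (a run of exactly
    the threshold duration — e.g. 50 frames at 25 fps vs 2 s — is
    non-cancer; 51 frames is cancer).
    """
    decisions = [bool(d.is_cancer) if isinstance(d, FrameDecision) else bool(d)
                 for d in frame_decisions]
    if len(decisions) == 0:
        raise ValueError("empty frame-decision sequence")
    if fps <= 0:
        raise ValueError("fps must be positive")
    run = longest_run(decisions, gap_tolerance=gap_tolerance)
    seconds = run / fps
    return VideoDiagnosis(
        is_cancer=bool(seconds > duration_threshold),
        longest_run_frames=int(run),
        longest_run_seconds=float(seconds),
        fps=float(fps),
        n_frames=len(decisions),
    )


def stream_diagnose(
    frames: Iterable[Frame],
    model,
    fps: float,
    probability_threshold: float = 0.5,
    area_threshold: Optional[float] = None,
    structuring_element_size: int = 5,
    duration_threshold: float = DEFAULT_DURATION_THRESHOLD,
    batch_size: int = 16,
    gap_tolerance: int = 0,
):
    """Run the full per-frame pipeline over a video and apply the 2 s rule.

    Per frame: segment → morphological cleanup → area-threshold call; then
    the consecutive-duration rule over the ordered calls.  When
    ``area_threshold`` is None it is scaled from the 32×32-at-512×512 rule
    to the model's working resolution.  Frames are processed in batches
    for throughput; per-frame wall-clock latency is returned for
    information only.

    Returns ``(VideoDiagnosis, decision_log, latencies)`` with one
    :class:`FrameDecision` and one latency (seconds) per frame.
    """
    import time

    from .io import Modality
    from .unet import predict_batch
    from skimage.transform import resize as _sk_resize

    frames = list(frames)
    if not frames:
        raise ValueError("empty video")
    size = model.spec.input_size
    if area_threshold is None:
        area_threshold = scaled_area_threshold(size)

    decision_log: list[FrameDecision] = []
    latencies: list[float] = []
    for start in range(0, len(frames), batch_size):
        chunk = frames[start : start + batch_size]
        imgs = []
        for f in chunk:
            img = np.asarray(f.image)
            if img.shape[:2] != size:
                img = _sk_resize(img, size, order=1, preserve_range=True,
                                 anti_aliasing=True).astype(np.uint8)
            imgs.append(img)
        mod_idx = np.array([0 if f.modality is Modality.WLI else 1 for f in chunk])
        t0 = time.perf_counter()
        probs = predict_batch(model, np.stack(imgs), modality_idx=mod_idx)
        elapsed = time.perf_counter() - t0
        for prob in probs:
            t1 = time.perf_counter()
            mask = (prob > probability_threshold).astype(np.uint8)
            mask = clean_mask(mask, structuring_element_size)
            decision_log.append(classify_frame(mask, area_threshold))
            latencies.append(elapsed / len(chunk) + (time.perf_counter() - t1))
    diagnosis = diagnose_video(
        [d.is_cancer for d in decision_log], fps, duration_threshold,
        gap_tolerance=gap_tolerance,
    )
    return diagnosis, decision_log, latencies


def select_duration_threshold(
    longest_run_seconds,
    truth_labels,
    grid: DurationThresholdGrid = DurationThresholdGrid(),
):
    """Pick the duration threshold by exhaustive grid evaluation.

    ``longest_run_seconds`` are per-video longest consecutive-positive run
    durations on the verification videos; selection metric is accuracy,
    ties break toward the smaller (more sensitive) threshold.  Returns
    ``(selected, table)``.
    """
    runs = np.asarray(longest_run_seconds, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if runs.shape != truth.shape:
        raise ValueError("runs and truth_labels must align")
    if truth.all() or not truth.any():
        raise ValueError("verification videos must contain both classes")
    if grid.metric != "accuracy":
        raise ValueError(f"unsupported selection metric {grid.metric!r}")
    rows = []
    for thr in grid.candidates:
        calls = runs > thr
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
    best = float(table.loc[table["accuracy"].idxmax(), "threshold"])
    return best, table
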