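"""Capture preprocessing: face-local coordinates, mean filtering, trimming.

The fixed stage order is shift → filter → trim.  Shifting subtracts a
reference landmark (the face "vertex") from every point so captures become
comparable across subjects regardless of where the head sat relative to the
camera; mean filtering suppresses sensor and muscle-tremor noise; trimming
drops the unsettled first/last 5 s (150 frames at 30 Hz) — which also
discards any filter edge effects — and standardizes every sample to the same
retained length (2112 frames at defaults) so the sliding-window feature grid
is identical for all subjects.  Samples left shorter than the retained
length are flagged discarded, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core_io import LandmarkSequence, PipelineConfig

__all__ = [
    "PreprocessReport",
    "shift_to_reference",
    "mean_filter",
    "trim_and_standardize",
    "preprocess_sequence",
]


@dataclass
class PreprocessReport:
    """Per-sample accounting of the preprocessing stage."""

    subject_id: str
    frames_in: int
    frames_trimmed_each_end: int
    frames_out: int
    discarded: bool
    filter_window_used: int


def shift_to_reference(
    seq: LandmarkSequence, reference_point: int = 0, mode: str = "per_frame"
) -> LandmarkSequence:
    """Express all landmarks relative to one reference landmark.

    ``per_frame`` (default) subtracts the reference point's position in each
    frame — removing rigid head translation frame by frame; ``first_frame``
    subtracts only its frame-0 position, preserving head motion.
    """
    if not 0 <= reference_point < seq.n_points:
        raise ValueError(
            f"reference_point {reference_point} out of range 0..{seq.n_points - 1}"
        )
    if mode == "per_frame":
        origin = seq.coords[:, reference_point : reference_point + 1, :]
    elif mode == "first_frame":
        origin = seq.coords[0:1, reference_point : reference_point + 1, :]
    else:
        raise ValueError(f"unknown shift mode {mode!r}")
    return seq.replace_coords(seq.coords - origin)


def mean_filter(seq: LandmarkSequence, W: int) -> LandmarkSequence:
    """Centered moving average of width ``W`` (3 or 5) along the frame axis.

    Near the boundaries the window is truncated to the in-range frames and
    the mean is taken over those, so the frame count is unchanged and no
    padding value leaks in.
    """
    if W % 2 == 0:
        raise ValueError("filter window W must be odd")
    if W not in (3, 5):
        raise ValueError("filter window W must be 3 or 5")
    n = seq.n_frames
    if W > n:
        raise ValueError(f"filter window {W} exceeds sequence length {n}")
    # windowed sum via zero-padded uniform filter, then divide by the number
    # of frames actually inside the window at each position
    sums = uniform_filter1d(seq.coords, W, axis=0, mode="constant", cval=0.0) * W
    counts = uniform_filter1d(np.ones(n), W, mode="constant", cval=0.0) * W
    return seq.replace_coords(sums / counts[:, None, None])


def trim_and_standardize(
    seq: LandmarkSequence, trim_seconds: float, retained_frames: int
) -> tuple[LandmarkSequence | None, PreprocessReport]:
    """Drop ``trim_seconds`` from each end, keep the first ``retained_frames``.

    Returns ``(None, report)`` with ``report.discarded = True`` when fewer
    than ``retained_frames`` frames survive the trim (the study protocol
    discards such captures rather than padding them).
    """
    trim = round(trim_seconds * seq.sample_rate_hz)
    remaining = seq.n_frames - 2 * trim
    if remaining < retained_frames:
        report = PreprocessReport(
            seq.subject_id, seq.n_frames, trim, max(remaining, 0), True, 0
        )
        return None, report
    trimmed = seq.replace_coords(seq.coords[trim : trim + retained_frames])
    report = PreprocessReport(
        seq.subject_id, seq.n_frames, trim, retained_frames, False, 0
    )
    return trimmed, report


def preprocess_sequence(
    seq: LandmarkSequence, cfg: PipelineConfig
) -> tuple[LandmarkSequence | None, PreprocessReport]:
    """Full chain shift → mean filter → trim under one config."""
    shifted = shift_to_reference(seq, cfg.reference_point, cfg.shift_mode)
    filtered = mean_filter(shifted, cfg.filter_window)
    out, report = trim_and_standardize(filtered, cfg.trim_seconds, cfg.retained_frames)
    report.filter_window_used = cfg.filter_window
    return out, report
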