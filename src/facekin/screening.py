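"""Landmark screening by inter-frame displacement variance.

Of the 1347 tracked landmarks most barely move during speech; modeling all
of them mainly adds noise dimensions.  Screening ranks every landmark by how
*variably* it moves: for each sample, the Euclidean displacement of each
point between consecutive frames gives an ``(N-1) x P`` matrix ``D``; the
sample variance of each column is that sample's per-point motion-variability
profile; profiles are stacked across the corpus and landmarks are ranked by
the column mean, descending.  The top ``top_points`` (100 at full
resolution) are kept for feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import LandmarkSequence

__all__ = [
    "DisplacementMatrix",
    "ScreeningResult",
    "frame_displacements",
    "point_variance",
    "rank_and_select",
    "screen_corpus",
]


@dataclass
class DisplacementMatrix:
    """Per-frame-step Euclidean displacement of every point, one sample."""

    subject_id: str
    values: np.ndarray  # shape (N-1, P), meters, >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("displacement matrix must be 2-D")
        if (self.values < 0).any():
            raise ValueError("displacements must be non-negative")


@dataclass
class ScreeningResult:
    """Corpus-level ranking of landmarks by mean displacement variance."""

    corpus_variance: np.ndarray  # (n_samples, P): per-sample sigma_j rows
    mean_variance: np.ndarray  # (P,)
    ranking: np.ndarray  # (P,) point indices, descending mean variance
    selected: np.ndarray  # (top_points,) = ranking[:top_points]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_variance": self.mean_variance.tolist(),
            "ranking": self.ranking.tolist(),
            "selected": self.selected.tolist(),
            "n_samples": int(self.corpus_variance.shape[0]),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreeningResult":
        payload = json.loads(Path(path).read_text())
        mean_variance = np.asarray(payload["mean_variance"], dtype=float)
        return cls(
            corpus_variance=np.empty((0, mean_variance.size)),
            mean_variance=mean_variance,
            ranking=np.asarray(payload["ranking"], dtype=int),
            selected=np.asarray(payload["selected"], dtype=int),
        )


def frame_displacements(seq: LandmarkSequence) -> DisplacementMatrix:
    """Euclidean distance each point travels between consecutive frames.

    Row *i* of the result is the displacement from frame *i* to *i+1*, so a
    sequence of N frames yields N-1 rows.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to compute displacements")
    diffs = np.diff(seq.coords, axis=0)
    return DisplacementMatrix(seq.subject_id, np.linalg.norm(diffs, axis=2))


def point_variance(d: DisplacementMatrix) -> np.ndarray:
    """Sample variance (denominator count-1) of each point's displacements."""
    if d.values.shape[0] < 2:
        raise ValueError("need at least 2 displacement rows for a variance")
    return d.values.var(axis=0, ddof=1)


def rank_and_select(
    per_sample_sigmas: Sequence[np.ndarray], top_points: int
) -> ScreeningResult:
    """Stack per-sample variance profiles, rank landmarks, keep the top.

    Ranking is by corpus-mean variance, descending; exact ties break toward
    the lower point index.
    """
    sigmas = [np.asarray(s, dtype=float) for s in per_sample_sigmas]
    if not sigmas:
        raise ValueError("no variance profiles supplied")
    p = sigmas[0].size
    if any(s.shape != (p,) for s in sigmas):
        raise ValueError("all variance profiles must have the same length")
    if not 1 <= top_points <= p:
        raise ValueError(f"top_points must be in 1..{p}")
    corpus = np.vstack(sigmas)
    mean_variance = corpus.mean(axis=0)
    # stable sort on the negated key keeps ascending index order within ties
    ranking = np.argsort(-mean_variance, kind="stable")
    return ScreeningResult(corpus, mean_variance, ranking, ranking[:top_points])


def screen_corpus(
    seqs: Iterable[LandmarkSequence], top_points: int
) -> ScreeningResult:
    """Convenience: displacement → variance per sample, then rank and select."""
    sigmas = [point_variance(frame_displacements(s)) for s in seqs]
    return rank_and_select(sigmas, top_points)
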