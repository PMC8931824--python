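"""Domain types, file I/O and questionnaire scoring.

The package works on two kinds of records:

* :class:`LandmarkSequence` — one subject's facial capture, a dense array of
  ``frames x points x 3`` coordinates in meters at a fixed sampling rate
  (30 Hz for the Kinect HD-face stream, 1347 points at full resolution).
* :class:`GDMSRecord` — the subject's General Decision-Making Style (GDMS)
  questionnaire result: five integer dimension scores (spontaneous, avoidant,
  rational, dependent, intuition), each the unweighted sum of five 1–5 Likert
  items, hence in [5, 25].

Landmark captures are interchanged as long-format CSV
(``frame,point,x,y,z``, 0-based indices, one file per subject); scores as a
flat CSV with one row per subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "AXES",
    "LandmarkSequence",
    "GDMSRecord",
    "PipelineConfig",
    "read_landmark_table",
    "write_landmark_table",
    "read_gdms_scores",
    "write_gdms_scores",
    "score_gdms_items",
]

#: The five GDMS dimensions, in canonical column order.
DIMENSIONS: tuple[str, ...] = (
    "spontaneous",
    "avoidant",
    "rational",
    "dependent",
    "intuition",
)

#: Axis order used everywhere in the package.
AXES: tuple[str, ...] = ("x", "y", "z")

SCORE_MIN, SCORE_MAX = 5, 25


@dataclass
class LandmarkSequence:
    """One subject's 3D facial-landmark capture.

    Parameters
    ----------
    subject_id
        Non-empty identifier.
    coords
        Array of shape ``(n_frames, n_points, 3)``, meters, axis order x,y,z.
    sample_rate_hz
        Capture rate; the Kinect face stream runs at 30 Hz.
    """

    subject_id: str
    coords: np.ndarray
    sample_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_points, 3); got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise ValueError("sequence needs at least one frame and one point")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def replace_coords(self, coords: np.ndarray) -> "LandmarkSequence":
        """New sequence with the same identity/rate but different coordinates."""
        return LandmarkSequence(self.subject_id, coords, self.sample_rate_hz)


@dataclass
class GDMSRecord:
    """Five GDMS dimension scores for one subject.

    ``items`` optionally holds the 25 raw Likert responses the scores were
    summed from; ``gender`` is optional metadata ("female"/"male").
    """

    subject_id: str
    scores: dict[str, int]
    items: list[int] | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        missing = [d for d in DIMENSIONS if d not in self.scores]
        if missing:
            raise ValueError(f"missing GDMS dimensions: {missing}")
        self.scores = {d: int(self.scores[d]) for d in DIMENSIONS}
        if self.items is not None and any(
            not (SCORE_MIN <= self.scores[d] <= SCORE_MAX) for d in DIMENSIONS
        ):
            raise ValueError("item-derived scores must lie in [5, 25]")
        if self.gender is not None and self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")


ALGORITHMS: tuple[str, ...] = ("lr", "svr", "ridgecv", "br")


@dataclass
class PipelineConfig:
    """All tunable constants of the recognition pipeline.

    Defaults follow the full-resolution study protocol: W=3 mean filter,
    5 s (150-frame) trims, 2112 retained frames, 128-frame FFT windows with a
    64-frame hop (32 windows per axis), top 100 landmarks, 80 PCA components,
    four score-quartile strata split 8:2, 10-fold CV.
    """

    filter_window: int = 3
    trim_seconds: float = 5.0
    retained_frames: int = 2112
    fft_window: int = 128
    fft_hop: int = 64
    top_points: int = 100
    pca_components: int = 80
    n_strata: int = 4
    train_fraction: float = 0.8
    cv_folds: int = 10
    algorithm: str = "lr"
    reference_point: int = 0
    shift_mode: str = "per_frame"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.filter_window not in (3, 5):
            raise ValueError("filter_window must be 3 or 5")
        if self.retained_frames < self.fft_window:
            raise ValueError("retained_frames must be >= fft_window")
        if (self.retained_frames - self.fft_window) % self.fft_hop != 0:
            raise ValueError(
                "fft_hop must divide (retained_frames - fft_window); "
                f"got {self.retained_frames}-{self.fft_window} vs hop {self.fft_hop}"
            )
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.shift_mode not in ("per_frame", "first_frame"):
            raise ValueError("shift_mode must be 'per_frame' or 'first_frame'")
        if self.top_points < 1 or self.pca_components < 1:
            raise ValueError("top_points and pca_components must be >= 1")

    @property
    def n_windows(self) -> int:
        """Sliding-window count per axis series."""
        return (self.retained_frames - self.fft_window) // self.fft_hop + 1

    @property
    def trim_frames(self) -> int:
        """Frames removed from each end (150 at 5 s / 30 Hz)."""
        return round(self.trim_seconds * 30.0)

    @classmethod
    def toy(cls, **overrides) -> "PipelineConfig":
        """Small preset (window 64 / hop 32, 576 retained frames, 30 points)
        that exercises every stage in seconds."""
        base = dict(
            retained_frames=576,
            fft_window=64,
            fft_hop=32,
            top_points=30,
            pca_components=20,
            cv_folds=5,
        )
        base.update(overrides)
        return cls(**base)

    # -- flat key:value config file ------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name}: {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
            key, value = (s.strip() for s in line.split(":", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if types[key] in ("int", int):
                kwargs[key] = int(value)
            elif types[key] in ("float", float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Landmark CSV I/O
# ---------------------------------------------------------------------------

_LANDMARK_COLUMNS = ["frame", "point", "x", "y", "z"]


def read_landmark_table(
    path: str | Path,
    subject_id: str | None = None,
    sample_rate_hz: float = 30.0,
) -> LandmarkSequence:
    """Read a long-format landmark CSV (``frame,point,x,y,z``).

    Every (frame, point) pair in the grid ``0..N-1 x 0..P-1`` must be present
    exactly once; missing or duplicated pairs are an error, never imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if list(df.columns) != _LANDMARK_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_LANDMARK_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    for col in ("x", "y", "z"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    frames = df["frame"].to_numpy()
    points = df["point"].to_numpy()
    n_frames = int(frames.max()) + 1
    n_points = int(points.max()) + 1
    if len(df) != n_frames * n_points:
        raise ValueError(
            f"{path}: ragged coverage — {len(df)} rows for a "
            f"{n_frames}x{n_points} frame/point grid"
        )
    if df.duplicated(subset=["frame", "point"]).any():
        raise ValueError(f"{path}: duplicate (frame, point) rows")
    coords = np.full((n_frames, n_points, 3), np.nan)
    coords[frames, points] = df[["x", "y", "z"]].to_numpy()
    if np.isnan(coords).any():
        raise ValueError(f"{path}: ragged coverage — missing (frame, point) pairs")
    return LandmarkSequence(subject_id or path.stem, coords, sample_rate_hz)


def write_landmark_table(seq: LandmarkSequence, path: str | Path) -> None:
    """Write a sequence as long-format CSV, frame-major then point order."""
    n, p = seq.n_frames, seq.n_points
    frames = np.repeat(np.arange(n), p)
    points = np.tile(np.arange(p), n)
    flat = seq.coords.reshape(n * p, 3)
    df = pd.DataFrame(
        {"frame": frames, "point": points, "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Scores CSV I/O
# ---------------------------------------------------------------------------

def read_gdms_scores(path: str | Path) -> list[GDMSRecord]:
    """Read a scores CSV with columns ``subject_id`` + the five dimensions
    (order-insensitive; an optional ``gender`` column is carried through)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *DIMENSIONS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_id(s) {dupes}")
    records = []
    for _, row in df.iterrows():
        scores = {}
        for d in DIMENSIONS:
            value = row[d]
            if float(value) != int(value):
                raise ValueError(f"{path}: non-integer score {value!r} for {d}")
            scores[d] = int(value)
        gender = row["gender"] if "gender" in df.columns else None
        records.append(GDMSRecord(str(row["subject_id"]), scores, gender=gender))
    return records


def write_gdms_scores(records: Sequence[GDMSRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id, **r.scores}
        if r.gender is not None:
            row["gender"] = r.gender
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GDMS item scoring
# ---------------------------------------------------------------------------

def score_gdms_items(
    items: Sequence[int], key: Mapping[str, Sequence[int]]
) -> dict[str, int]:
    """Sum 25 Likert items (1–5) into five dimension scores.

    ``key`` maps each dimension name to the five 0-based item indices of its
    block; the blocks must partition 0..24. Each score is the plain sum of its
    five items, so scores range over [5, 25].
    """
    items = list(items)
    if len(items) != 25:
        raise ValueError(f"expected 25 items, got {len(items)}")
    for v in items:
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
            raise ValueError(f"item value {v!r} outside 1..5")
    if set(key) != set(DIMENSIONS):
        raise ValueError(f"key must cover exactly the dimensions {DIMENSIONS}")
    claimed = [i for d in DIMENSIONS for i in key[d]]
    if sorted(claimed) != list(range(25)) or any(len(key[d]) != 5 for d in DIMENSIONS):
        raise ValueError("key must partition item indices 0..24 into five blocks of 5")
    return {d: int(sum(items[i] for i in key[d])) for d in DIMENSIONS}
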