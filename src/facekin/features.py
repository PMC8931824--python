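"""Sliding-window FFT modulus features.

Each retained axis series (one coordinate of one selected landmark) is cut
into 50%-overlapping windows — 128 frames with a 64-frame hop at defaults,
hence ``(2112 - 128)/64 + 1 = 32`` windows — and each window is mapped to
two numbers: the mean and the sample variance of the moduli of its
unnormalized discrete Fourier coefficients.  With 100 selected landmarks,
3 axes, 32 windows and 2 statistics this yields the study's 19200 features
per sample.

The feature layout is deterministic and point-major: for each selected point
(in screening-rank order), for each axis x,y,z, for each window in time
order, the (mean, variance) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import AXES, LandmarkSequence, PipelineConfig

__all__ = [
    "WindowSpectrum",
    "FeatureLayout",
    "FeatureMatrix",
    "window_fft",
    "window_stats",
    "build_layout",
    "extract_sample_features",
    "extract_features",
]

STATISTICS: tuple[str, ...] = ("mean", "variance")


@dataclass
class WindowSpectrum:
    """DFT of one window: complex coefficients and their moduli."""

    coefficients: np.ndarray  # complex, length L
    moduli: np.ndarray  # |F_k| = sqrt(Re^2 + Im^2), length L


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered feature naming: (point_rank, axis, window_index, statistic).

    ``point_rank`` is the position in the screening ranking (0 = most
    variable landmark), not the raw landmark index, so layouts are
    comparable across cohorts of different sizes.
    """

    entries: tuple[tuple[int, str, int, str], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [f"p{p:03d}_{a}_w{w:02d}_{s}" for p, a, w, s in self.entries]


def build_layout(n_selected: int, n_windows: int) -> FeatureLayout:
    """Point-major, then axis, then window, then statistic."""
    entries = tuple(
        (p, a, w, s)
        for p in range(n_selected)
        for a in AXES
        for w in range(n_windows)
        for s in STATISTICS
    )
    return FeatureLayout(entries)


@dataclass
class FeatureMatrix:
    """Samples × spectral features, with the layout that names each column."""

    subject_ids: list[str]
    values: np.ndarray
    layout: FeatureLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.layout):
            raise ValueError(
                f"values shape {self.values.shape} does not match layout "
                f"length {len(self.layout)}"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject_id per row required")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.layout.names)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "subject_id"]
        entries = []
        for name in names:
            p, a, w, s = name.split("_")
            entries.append((int(p[1:]), a, int(w[1:]), s))
        return cls(
            subject_ids=[str(s) for s in df["subject_id"]],
            values=df[names].to_numpy(dtype=float),
            layout=FeatureLayout(tuple(entries)),
        )


def window_fft(x: np.ndarray, fft_window: int = 128) -> WindowSpectrum:
    """Unnormalized forward DFT of one window (no 1/L factor)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (fft_window,):
        raise ValueError(f"expected a length-{fft_window} window, got shape {x.shape}")
    coeffs = np.fft.fft(x)
    return WindowSpectrum(coeffs, np.abs(coeffs))


def window_stats(spec: WindowSpectrum) -> tuple[float, float]:
    """(mean, sample variance) of the window's coefficient moduli.

    Variance uses denominator L-1, matching the sample-variance convention
    used for displacement screening.
    """
    moduli = np.asarray(spec.moduli, dtype=float)
    return float(moduli.mean()), float(moduli.var(ddof=1))


def _window_starts(n_frames: int, cfg: PipelineConfig) -> np.ndarray:
    if n_frames < cfg.fft_window or (n_frames - cfg.fft_window) % cfg.fft_hop:
        raise ValueError(
            f"{n_frames} frames incompatible with window {cfg.fft_window} / "
            f"hop {cfg.fft_hop}"
        )
    return np.arange(0, n_frames - cfg.fft_window + 1, cfg.fft_hop)


def extract_sample_features(
    seq: LandmarkSequence, selected: Sequence[int], cfg: PipelineConfig
) -> tuple[np.ndarray, FeatureLayout]:
    """One sample's feature row in layout order.

    ``selected`` is the screening result's point list; its order defines the
    point-rank blocks of the row.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected point list must be non-empty")
    starts = _window_starts(seq.n_frames, cfg)
    n_win = starts.size
    # (n_win, L, n_sel, 3): every window of every selected series at once
    windows = np.stack([seq.coords[s : s + cfg.fft_window, selected, :] for s in starts])
    moduli = np.abs(np.fft.fft(windows, axis=1))
    means = moduli.mean(axis=1)  # (n_win, n_sel, 3)
    variances = moduli.var(axis=1, ddof=1)
    # reorder to point-major, axis, window, statistic
    stats = np.stack([means, variances], axis=-1)  # (n_win, n_sel, 3, 2)
    row = stats.transpose(1, 2, 0, 3).reshape(-1)
    return row, build_layout(selected.size, n_win)


def extract_features(
    seqs: Iterable[LandmarkSequence], selected: Sequence[int], cfg: PipelineConfig
) -> FeatureMatrix:
    """Feature rows for a corpus of preprocessed sequences."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    layout: FeatureLayout | None = None
    for seq in seqs:
        row, layout = extract_sample_features(seq, selected, cfg)
        ids.append(seq.subject_id)
        rows.append(row)
    if layout is None:
        raise ValueError("no sequences supplied")
    return FeatureMatrix(ids, np.vstack(rows), layout)
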