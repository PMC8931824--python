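"""Synthetic cohorts with a planted trait → facial-motion coupling.

The study data this package was designed for — 30 Hz Kinect captures of 1347
facial landmarks during a short speech, paired with GDMS questionnaire
scores — is not publicly deposited.  This module generates cohorts with the
same shape and a *recoverable* structure: each subject has five latent
standard-normal trait values ``z`` (one per GDMS dimension); the
questionnaire score for dimension *d* is ``round(mean_d + sd_d * z_d)``
clipped to [5, 25], and a subset of "signal" landmarks oscillates with
spectral amplitudes linearly modulated by the same ``z``.  A pipeline that
truly extracts spectral amplitude features and regresses them on scores must
therefore recover the planted coupling; one that is broken anywhere will not.

Generative model per subject
----------------------------
* a static face: per-point base positions in a head-sized box ~0.7 m from
  the camera;
* rigid head translation shared by all points: slow (< 0.2 Hz) sinusoidal
  drift of ~5 mm, so the face-local coordinate shift stage has real work;
* each signal point adds 2–4 sinusoids with frequencies in (0.5, 8) Hz —
  resolvable bins of a 128-frame window at 30 Hz — along fixed random 3D
  directions, with amplitude ``base_amplitude * (1 + coupling * <w_j, z>)``
  where ``w_j`` is a fixed per-point weight vector (see below);
* i.i.d. Gaussian measurement noise on every coordinate.

Per-point weights ``w_j`` are one-hot: signal point *j* carries dimension
``j mod 5`` with weight scale ``w_scale`` (default 0.2), so amplitude
factors stay positive for all plausible ``z`` and the feature→score map is
monotone.  Point-level parameters (weights, frequencies, directions) are
drawn once per cohort from the seed, so they are shared across subjects;
phases and noise are per-subject.

Score means/SDs default to the pooled study norms (per-gender means 15.20 to
19.90, SDs 2.61 to 4.86, pooled with cohort weights 130 female / 110 male).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .core_io import DIMENSIONS, GDMSRecord, LandmarkSequence

__all__ = [
    "GENDER_SCORE_NORMS",
    "pooled_score_norms",
    "SimulationConfig",
    "LatentTraits",
    "simulate_traits",
    "simulate_score_records",
    "simulate_sample",
    "simulate_cohort",
    "iter_cohort",
    "planted_signal_points",
]

#: Published per-gender GDMS norms: dimension -> gender -> (mean, sd).
GENDER_SCORE_NORMS: dict[str, dict[str, tuple[float, float]]] = {
    "spontaneous": {"female": (17.67, 4.60), "male": (15.66, 4.52)},
    "avoidant": {"female": (18.06, 2.61), "male": (19.90, 3.13)},
    "rational": {"female": (16.71, 4.33), "male": (15.20, 4.12)},
    "dependent": {"female": (15.21, 4.02), "male": (17.00, 4.86)},
    "intuition": {"female": (18.49, 3.53), "male": (17.05, 3.62)},
}

#: Cohort composition behind the pooled norms (130 female, 110 male).
GENDER_WEIGHTS: dict[str, int] = {"female": 130, "male": 110}


def pooled_score_norms() -> tuple[dict[str, float], dict[str, float]]:
    """Gender-pooled (mean, sd) per dimension.

    The pooled variance combines within-gender variance and the
    between-gender mean shift, weighted by cohort composition.
    """
    n_total = sum(GENDER_WEIGHTS.values())
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for dim, by_gender in GENDER_SCORE_NORMS.items():
        m = sum(GENDER_WEIGHTS[g] * mu for g, (mu, _) in by_gender.items()) / n_total
        var = (
            sum(
                GENDER_WEIGHTS[g] * (sd**2 + (mu - m) ** 2)
                for g, (mu, sd) in by_gender.items()
            )
            / n_total
        )
        means[dim] = m
        sds[dim] = float(np.sqrt(var))
    return means, sds


@dataclass
class SimulationConfig:
    """Cohort-generator settings; defaults match the study conditions."""

    n_subjects: int = 240
    n_points: int = 1347
    n_frames: int = 2500
    sample_rate_hz: float = 30.0
    n_signal_points: int = 100
    base_amplitude_m: float = 0.002
    coupling_strength: float = 1.0
    noise_sd_m: float = 0.0003
    w_scale: float = 0.2
    drift_amplitude_m: float = 0.005
    score_means: dict[str, float] = field(default_factory=lambda: pooled_score_norms()[0])
    score_sds: dict[str, float] = field(default_factory=lambda: pooled_score_norms()[1])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_points > self.n_points:
            raise ValueError("n_signal_points must be <= n_points")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if any(self.score_sds[d] <= 0 for d in DIMENSIONS):
            raise ValueError("all score SDs must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @classmethod
    def toy(cls, **overrides) -> "SimulationConfig":
        """Down-scaled preset: 60 points (20 of them signal), fewer subjects."""
        base = dict(n_subjects=20, n_points=60, n_signal_points=20, n_frames=900)
        base.update(overrides)
        return cls(**base)


@dataclass
class LatentTraits:
    """The latent standard-normal trait vector a subject's scores and facial
    motion are generated from; ground truth for recovery tests."""

    subject_id: str
    z: np.ndarray  # shape (5,), one value per GDMS dimension

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(DIMENSIONS),):
            raise ValueError(f"z must have shape ({len(DIMENSIONS)},)")
        if not np.isfinite(self.z).all():
            raise ValueError("z must be finite")


@dataclass
class _PointParams:
    """Cohort-level planted structure (shared by all subjects)."""

    signal_points: np.ndarray  # indices of signal landmarks
    weights: np.ndarray  # (n_signal, 5) one-hot * w_scale
    freqs: np.ndarray  # (n_signal, max_sin) Hz, NaN-padded
    directions: np.ndarray  # (n_signal, max_sin, 3) unit vectors
    base_positions: np.ndarray  # (n_points, 3)

    MAX_SINUSOIDS = 4


def _point_params(cfg: SimulationConfig) -> _PointParams:
    """Deterministic cohort-level structure derived from ``cfg.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5AFE]))
    # face-shaped cloud: ~16 cm wide/high, 8 cm deep, centered 0.7 m from camera
    base = rng.uniform(-0.08, 0.08, size=(cfg.n_points, 3))
    base[:, 2] = 0.70 + rng.uniform(-0.04, 0.04, size=cfg.n_points)
    signal_points = rng.choice(cfg.n_points, size=cfg.n_signal_points, replace=False)
    signal_points.sort()
    dims = np.arange(cfg.n_signal_points) % len(DIMENSIONS)
    weights = np.zeros((cfg.n_signal_points, len(DIMENSIONS)))
    weights[np.arange(cfg.n_signal_points), dims] = cfg.w_scale
    n_sin = rng.integers(2, _PointParams.MAX_SINUSOIDS + 1, size=cfg.n_signal_points)
    freqs = np.full((cfg.n_signal_points, _PointParams.MAX_SINUSOIDS), np.nan)
    directions = np.zeros((cfg.n_signal_points, _PointParams.MAX_SINUSOIDS, 3))
    for j in range(cfg.n_signal_points):
        freqs[j, : n_sin[j]] = rng.uniform(0.5, 8.0, size=n_sin[j])
        vec = rng.normal(size=(n_sin[j], 3))
        directions[j, : n_sin[j]] = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    return _PointParams(signal_points, weights, freqs, directions, base)


def planted_signal_points(cfg: SimulationConfig) -> np.ndarray:
    """Indices of the landmarks whose oscillation carries trait signal."""
    return _point_params(cfg).signal_points.copy()


def simulate_traits(cfg: SimulationConfig) -> list[LatentTraits]:
    """Draw the cohort's latent trait vectors (standard normal, i.i.d.)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x712A17]))
    return [
        LatentTraits(f"S{i:04d}", rng.standard_normal(len(DIMENSIONS)))
        for i in range(cfg.n_subjects)
    ]


def _amplitude_factors(params: _PointParams, z: np.ndarray, coupling: float) -> np.ndarray:
    """Per-signal-point amplitude multipliers ``1 + coupling * <w_j, z>``,
    floored at 0.05 so amplitudes stay physical."""
    return np.maximum(1.0 + coupling * params.weights @ z, 0.05)


def simulate_sample(
    traits: LatentTraits,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    params: _PointParams | None = None,
) -> LandmarkSequence:
    """Generate one subject's landmark capture.

    ``rng`` supplies all subject-level randomness (phases, drift, head
    placement, noise); the cohort-level structure comes from ``cfg.seed``
    via ``params`` (recomputed if not supplied).
    """
    if params is None:
        params = _point_params(cfg)
    n, p = cfg.n_frames, cfg.n_points
    t = np.arange(n) / cfg.sample_rate_hz

    # head placement + slow rigid drift shared by every point
    head_offset = rng.uniform(-0.05, 0.05, size=3)
    drift = np.zeros((n, 3))
    for _ in range(2):
        f = rng.uniform(0.02, 0.2)
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        drift += (
            cfg.drift_amplitude_m
            * np.sin(2 * np.pi * f * t + phase)[:, None]
            * direction[None, :]
        )

    coords = np.empty((n, p, 3))
    coords[:] = params.base_positions[None, :, :] + head_offset[None, None, :]
    coords += drift[:, None, :]

    factors = _amplitude_factors(params, traits.z, cfg.coupling_strength)
    for idx, j in enumerate(params.signal_points):
        live = ~np.isnan(params.freqs[idx])
        phases = rng.uniform(0, 2 * np.pi, size=live.sum())
        osc = np.zeros((n, 3))
        for k, (f, phi) in enumerate(zip(params.freqs[idx, live], phases)):
            osc += (
                np.sin(2 * np.pi * f * t + phi)[:, None]
                * params.directions[idx, k][None, :]
            )
        coords[:, j, :] += cfg.base_amplitude_m * factors[idx] * osc

    if cfg.noise_sd_m > 0:
        coords += rng.normal(scale=cfg.noise_sd_m, size=coords.shape)
    return LandmarkSequence(traits.subject_id, coords, cfg.sample_rate_hz)


def simulate_score_records(
    traits: Sequence[LatentTraits], cfg: SimulationConfig
) -> list[GDMSRecord]:
    """GDMS records implied by a trait draw: round(mean + sd*z), clipped to [5, 25]."""
    records = []
    for tr in traits:
        scores = {}
        for d_idx, dim in enumerate(DIMENSIONS):
            raw = cfg.score_means[dim] + cfg.score_sds[dim] * tr.z[d_idx]
            scores[dim] = int(np.clip(round(raw), 5, 25))
        records.append(GDMSRecord(tr.subject_id, scores))
    return records


def iter_cohort(
    cfg: SimulationConfig,
) -> Iterator[tuple[LandmarkSequence, GDMSRecord, LatentTraits]]:
    """Stream (sequence, scores, traits) triples one subject at a time.

    Subjects are generated from independent child streams of ``cfg.seed``,
    so subject *i* is identical no matter how many subjects are requested.
    """
    params = _point_params(cfg)
    traits = simulate_traits(cfg)
    records = simulate_score_records(traits, cfg)
    children = np.random.SeedSequence([cfg.seed, 0xC0FFEE]).spawn(cfg.n_subjects)
    for tr, rec, child in zip(traits, records, children):
        rng = np.random.default_rng(child)
        yield simulate_sample(tr, cfg, rng, params), rec, tr


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[LandmarkSequence], list[GDMSRecord], list[LatentTraits]]:
    """Materialize a full cohort (see :func:`iter_cohort` for streaming)."""
    seqs, records, traits = [], [], []
    for seq, rec, tr in iter_cohort(cfg):
        seqs.append(seq)
        records.append(rec)
        traits.append(tr)
    return seqs, records, traits
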