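"""Model fitting and evaluation: stratified splits, PCA + linear regressors,
cross-validation, Pearson/RMSE metrics, and odd/even-frame split-half
reliability.

The regression problem is samples × 19200 spectral features → one integer
questionnaire score per GDMS dimension, with far fewer samples (~236) than
features, so the pipeline is: center on the training mean, project onto a
PCA basis fitted on training rows only (80 components at defaults, chosen in
the study to carry >98% of the variance), standardize the component scores,
and fit one of four linear regressors:

``lr``
    ordinary least squares;
``svr``
    epsilon-insensitive support-vector regression with a linear kernel
    (C = 1, epsilon = 0.1·SD of the training scores);
``ridgecv``
    L2-penalized least squares with the penalty picked by efficient
    leave-one-out generalized cross-validation over a logarithmic grid;
``br``
    Bayesian linear regression with conjugate Gamma hyperpriors estimated
    by evidence maximization.

Train/validation splitting is stratified on the score: samples are sorted
by score, cut into four quartile strata (60 each at n=240), and 80% of each
stratum is drawn for training (48/12 per stratum; 192/48 overall), so both
sets cover the full score range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import BayesianRidge, LinearRegression, RidgeCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .core_io import ALGORITHMS, DIMENSIONS, GDMSRecord, LandmarkSequence, PipelineConfig
from .features import FeatureMatrix, extract_features
from .screening import ScreeningResult

__all__ = [
    "SplitPlan",
    "ModelBundle",
    "EvaluationReport",
    "RIDGE_ALPHAS",
    "stratified_split",
    "fit_pipeline",
    "predict",
    "evaluate",
    "crossvalidate",
    "split_half_reliability",
    "holdout_report",
]

logger = logging.getLogger(__name__)

#: Penalty grid searched by generalized cross-validation for ``ridgecv``.
RIDGE_ALPHAS: np.ndarray = np.logspace(-3, 3, 13)

PCA_VARIANCE_FLOOR = 0.98


@dataclass
class SplitPlan:
    """Score-stratified train/validation assignment for one dimension."""

    dimension: str
    strata: list[list[str]]  # subject_ids per stratum, score-descending blocks
    train_ids: list[str]
    val_ids: list[str]


def stratified_split(
    records: Sequence[GDMSRecord],
    dimension: str,
    n_strata: int = 4,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Sort by score (descending, ties by subject id), cut into ``n_strata``
    contiguous blocks, and draw ``train_fraction`` of each block uniformly
    at random for training.

    Block sizes are ``n // n_strata`` with the remainder going to the
    highest-score blocks.  The per-stratum training count is
    ``round(train_fraction * size)``.
    """
    if not records:
        raise ValueError("no records supplied")
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(records) < n_strata:
        raise ValueError("need at least one record per stratum")
    ordered = sorted(records, key=lambda r: (-r.scores[dimension], r.subject_id))
    n = len(ordered)
    base, extra = divmod(n, n_strata)
    sizes = [base + (1 if i < extra else 0) for i in range(n_strata)]
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, DIMENSIONS.index(dimension)])
    )
    strata: list[list[str]] = []
    train_ids: list[str] = []
    val_ids: list[str] = []
    cursor = 0
    for size in sizes:
        block = [r.subject_id for r in ordered[cursor : cursor + size]]
        cursor += size
        n_train = round(train_fraction * size)
        chosen = set(rng.choice(size, size=n_train, replace=False).tolist())
        strata.append(block)
        train_ids.extend(sid for i, sid in enumerate(block) if i in chosen)
        val_ids.extend(sid for i, sid in enumerate(block) if i not in chosen)
    return SplitPlan(dimension, strata, train_ids, val_ids)


def _make_regressor(algorithm: str, train_scores: np.ndarray, ridge_alphas=None):
    if algorithm == "lr":
        return LinearRegression()
    if algorithm == "svr":
        return SVR(kernel="linear", C=1.0, epsilon=0.1 * float(np.std(train_scores)))
    if algorithm == "ridgecv":
        alphas = RIDGE_ALPHAS if ridge_alphas is None else np.asarray(ridge_alphas)
        return RidgeCV(alphas=alphas, gcv_mode="auto")
    if algorithm == "br":
        return BayesianRidge()
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


@dataclass
class ModelBundle:
    """A fitted PCA + regressor pipeline for one dimension.

    Prediction is a pure function of a feature row: center on the stored
    training mean, project onto the PCA basis, standardize the component
    scores with the stored moments, apply the regressor.
    """

    dimension: str
    algorithm: str
    pca: PCA
    scaler: StandardScaler
    model: object
    layout_len: int
    fitted_on: list[str]
    config: PipelineConfig
    explained_variance: float

    @property
    def pca_mean(self) -> np.ndarray:
        return self.pca.mean_

    @property
    def pca_basis(self) -> np.ndarray:
        """Orthonormal components, shape (n_components, n_features)."""
        return self.pca.components_


def fit_pipeline(
    train_features: FeatureMatrix,
    train_scores: Sequence[float],
    cfg: PipelineConfig,
    dimension: str = "",
    ridge_alphas=None,
) -> ModelBundle:
    """Fit centering, PCA basis and regressor on training rows only."""
    x = train_features.values
    y = np.asarray(train_scores, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("one score per training row required")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    max_components = min(x.shape[0] - 1, x.shape[1])
    if cfg.pca_components > max_components:
        raise ValueError(
            f"pca_components={cfg.pca_components} exceeds the maximum "
            f"{max_components} for a {x.shape[0]}x{x.shape[1]} training matrix"
        )
    pca = PCA(n_components=cfg.pca_components, svd_solver="full", random_state=0)
    projected = pca.fit_transform(x)
    explained = float(pca.explained_variance_ratio_.sum())
    logger.info(
        "PCA %d -> %d components, explained variance %.4f",
        x.shape[1], cfg.pca_components, explained,
    )
    if explained < PCA_VARIANCE_FLOOR:
        logger.warning(
            "PCA explained variance %.4f below the %.2f design floor",
            explained, PCA_VARIANCE_FLOOR,
        )
    scaler = StandardScaler().fit(projected)
    model = _make_regressor(cfg.algorithm, y, ridge_alphas)
    model.fit(scaler.transform(projected), y)
    return ModelBundle(
        dimension=dimension,
        algorithm=cfg.algorithm,
        pca=pca,
        scaler=scaler,
        model=model,
        layout_len=len(train_features.layout),
        fitted_on=list(train_features.subject_ids),
        config=cfg,
        explained_variance=explained,
    )


def predict(bundle: ModelBundle, features: FeatureMatrix) -> np.ndarray:
    """Apply a fitted bundle to new feature rows."""
    if len(features.layout) != bundle.layout_len:
        raise ValueError(
            f"feature layout length {len(features.layout)} does not match "
            f"the fitted layout length {bundle.layout_len}"
        )
    projected = bundle.pca.transform(features.values)
    return np.asarray(bundle.model.predict(bundle.scaler.transform(projected)), dtype=float)


def evaluate(pred: Sequence[float], actual: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and RMSE between predictions and actual scores.

    A constant ``actual`` (or constant predictions) leaves Pearson r
    undefined; it is reported as NaN with a warning, never raised.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError("pred and actual must be 1-D vectors of equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs to evaluate")
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    if np.std(actual) == 0 or np.std(pred) == 0:
        warnings.warn("Pearson r undefined for a constant vector; reporting NaN")
        return float("nan"), rmse
    r = float(stats.pearsonr(pred, actual).statistic)
    return r, rmse


def crossvalidate(
    features: FeatureMatrix,
    scores: Sequence[float],
    cfg: PipelineConfig,
) -> list[tuple[float, float]]:
    """Seeded k-fold cross-validation; PCA is refitted inside every fold."""
    y = np.asarray(scores, dtype=float)
    n = y.size
    if n < cfg.cv_folds:
        raise ValueError(f"need at least cv_folds={cfg.cv_folds} samples, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF01D]))
    order = rng.permutation(n)
    folds = np.array_split(order, cfg.cv_folds)
    results = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train = FeatureMatrix(
            [features.subject_ids[i] for i in np.flatnonzero(mask)],
            features.values[mask],
            features.layout,
        )
        test = FeatureMatrix(
            [features.subject_ids[i] for i in fold],
            features.values[fold],
            features.layout,
        )
        bundle = fit_pipeline(train, y[mask], cfg)
        results.append(evaluate(predict(bundle, test), y[fold]))
    return results


def _subset(features: FeatureMatrix, ids: Sequence[str]) -> FeatureMatrix:
    index = {sid: i for i, sid in enumerate(features.subject_ids)}
    rows = [index[sid] for sid in ids]
    return FeatureMatrix(list(ids), features.values[rows], features.layout)


def split_half_reliability(
    sequences: Sequence[LandmarkSequence],
    records: Sequence[GDMSRecord],
    screening: ScreeningResult,
    cfg: PipelineConfig,
    spearman_brown: bool = False,
) -> dict[str, float]:
    """Internal-consistency estimate from odd/even-frame half-captures.

    Each preprocessed capture (2112 frames at defaults) is split into its
    even-index and odd-index frames (1056 each).  Because the windowed
    feature grid changes at half length, two parallel pipelines with the FFT
    window and hop halved (preserving the 32-window count) are trained on
    the training halves; the per-dimension reliability is the Pearson
    correlation between the two pipelines' validation predictions,
    optionally Spearman–Brown corrected (2r / (1+r)).
    """
    if cfg.retained_frames % 2:
        raise ValueError("retained_frames must be even for an odd/even split")
    half_cfg = replace(
        cfg,
        retained_frames=cfg.retained_frames // 2,
        fft_window=cfg.fft_window // 2,
        fft_hop=cfg.fft_hop // 2,
    )
    selected = screening.selected
    even = [s.replace_coords(s.coords[0::2]) for s in sequences]
    odd = [s.replace_coords(s.coords[1::2]) for s in sequences]
    feats_even = extract_features(even, selected, half_cfg)
    feats_odd = extract_features(odd, selected, half_cfg)
    score_by_id = {r.subject_id: r.scores for r in records}
    out: dict[str, float] = {}
    for dim in DIMENSIONS:
        plan = stratified_split(
            records, dim, cfg.n_strata, cfg.train_fraction, cfg.seed
        )
        y_train = [score_by_id[sid][dim] for sid in plan.train_ids]
        preds = []
        for half_feats in (feats_even, feats_odd):
            bundle = fit_pipeline(
                _subset(half_feats, plan.train_ids), y_train, half_cfg, dim
            )
            preds.append(predict(bundle, _subset(half_feats, plan.val_ids)))
        r, _ = evaluate(preds[0], preds[1])
        if spearman_brown and np.isfinite(r):
            r = 2 * r / (1 + r)
        out[dim] = r
    return out


@dataclass
class EvaluationReport:
    """Tidy per-(dimension, algorithm, W) metrics table.

    Columns: dimension, algorithm, W, metric, value — with metrics
    ``pearson_r``, ``rmse`` and optionally ``cv_fold_r``/``cv_fold_rmse``
    (one row per fold) and ``split_half_r``.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["dimension", "algorithm", "W", "metric", "value"]
        )
    )

    def add(self, dimension: str, algorithm: str, w: int, metric: str, value: float) -> None:
        self.table.loc[len(self.table)] = [dimension, algorithm, w, metric, value]

    def pivot(self, metric: str = "pearson_r") -> pd.DataFrame:
        sub = self.table[self.table.metric == metric]
        return sub.pivot_table(
            index=["algorithm", "W"], columns="dimension", values="value"
        ).reindex(columns=list(DIMENSIONS))

    def summary(self, metric: str = "pearson_r") -> pd.DataFrame:
        """Per-(algorithm, W) mean and SD across the five dimensions."""
        wide = self.pivot(metric)
        return pd.DataFrame({"M": wide.mean(axis=1), "SD": wide.std(axis=1)})

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def holdout_report(
    features: FeatureMatrix,
    records: Sequence[GDMSRecord],
    cfg: PipelineConfig,
    algorithms: Sequence[str] = ALGORITHMS,
    shared_split: bool = False,
) -> EvaluationReport:
    """Stratified 8:2 holdout evaluation, every dimension × algorithm.

    By default each dimension gets its own score-stratified split; with
    ``shared_split`` the spontaneous-dimension split serves all five.
    """
    report = EvaluationReport()
    score_by_id = {r.subject_id: r.scores for r in records}
    shared_plan = (
        stratified_split(records, DIMENSIONS[0], cfg.n_strata, cfg.train_fraction, cfg.seed)
        if shared_split
        else None
    )
    for dim in DIMENSIONS:
        plan = shared_plan or stratified_split(
            records, dim, cfg.n_strata, cfg.train_fraction, cfg.seed
        )
        y_train = [score_by_id[sid][dim] for sid in plan.train_ids]
        y_val = np.asarray([score_by_id[sid][dim] for sid in plan.val_ids], dtype=float)
        train_feats = _subset(features, plan.train_ids)
        val_feats = _subset(features, plan.val_ids)
        for algorithm in algorithms:
            algo_cfg = replace(cfg, algorithm=algorithm)
            bundle = fit_pipeline(train_feats, y_train, algo_cfg, dim)
            r, rmse = evaluate(predict(bundle, val_feats), y_val)
            report.add(dim, algorithm, cfg.filter_window, "pearson_r", r)
            report.add(dim, algorithm, cfg.filter_window, "rmse", rmse)
    return report
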