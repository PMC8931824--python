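"""Stratified splits, PCA + regressor pipelines, metrics and reliability."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import facekin as fk
from facekin.core_io import DIMENSIONS
from facekin.features import FeatureMatrix, build_layout
from facekin.modeling import (
    RIDGE_ALPHAS,
    crossvalidate,
    evaluate,
    fit_pipeline,
    predict,
    split_half_reliability,
    stratified_split,
)


def _records(scores_by_dim):
    n = len(next(iter(scores_by_dim.values())))
    out = []
    for i in range(n):
        out.append(
            fk.GDMSRecord(
                f"s{i:04d}",
                {d: int(scores_by_dim.get(d, [15] * n)[i]) for d in DIMENSIONS},
            )
        )
    return out


def _feature_matrix(values, n_windows=2):
    values = np.asarray(values, dtype=float)
    n_points = values.shape[1] // (3 * n_windows * 2)
    layout = build_layout(n_points, n_windows)
    assert len(layout) == values.shape[1]
    return FeatureMatrix([f"s{i:04d}" for i in range(values.shape[0])], values, layout)


class TestStratifiedSplit:
    def test_study_counts(self, rng):
        records = _records({"spontaneous": rng.integers(5, 26, size=240)})
        plan = stratified_split(records, "spontaneous", seed=1)
        assert [len(s) for s in plan.strata] == [60, 60, 60, 60]
        assert len(plan.train_ids) == 192 and len(plan.val_ids) == 48
        for stratum in plan.strata:
            in_train = sum(sid in set(plan.train_ids) for sid in stratum)
            assert in_train == 48
        assert sorted(plan.train_ids + plan.val_ids) == sorted(r.subject_id for r in records)

    def test_strata_are_score_ordered(self, rng):
        records = _records({"rational": rng.integers(5, 26, size=40)})
        plan = stratified_split(records, "rational", seed=0)
        by_id = {r.subject_id: r.scores["rational"] for r in records}
        mins_maxes = [(min(map(by_id.get, s)), max(map(by_id.get, s))) for s in plan.strata]
        for earlier, later in zip(mins_maxes[:-1], mins_maxes[1:]):
            assert earlier[0] >= later[1]  # strata run from high scores to low

    def test_determinism_and_seed_sensitivity(self, rng):
        records = _records({"avoidant": rng.integers(5, 26, size=80)})
        a = stratified_split(records, "avoidant", seed=3)
        b = stratified_split(records, "avoidant", seed=3)
        c = stratified_split(records, "avoidant", seed=4)
        assert a.train_ids == b.train_ids and a.val_ids == b.val_ids
        assert a.strata == c.strata  # strata depend only on scores
        assert a.train_ids != c.train_ids

    def test_rounding_in_small_stratum(self, rng):
        records = _records({"intuition": rng.integers(5, 26, size=10)})
        plan = stratified_split(records, "intuition", n_strata=1, train_fraction=0.8, seed=0)
        assert len(plan.train_ids) == 8 and len(plan.val_ids) == 2

    def test_errors(self):
        with pytest.raises(ValueError):
            stratified_split([], "rational")
        records = _records({"rational": [10, 12, 14, 16, 18, 20]})
        with pytest.raises(ValueError):
            stratified_split(records, "rational", train_fraction=1.0)
        with pytest.raises(ValueError):
            stratified_split(records, "nope")


class TestFitPredict:
    def test_exact_linear_interpolation(self, rng):
        x = rng.normal(size=(30, 24))
        beta = np.zeros(24)
        beta[[0, 3, 7, 11, 19]] = rng.normal(size=5)
        y = x @ beta + 1.5
        cfg = fk.PipelineConfig.toy(pca_components=24, top_points=2)
        feats = _feature_matrix(x)
        bundle = fit_pipeline(feats, y, cfg)
        np.testing.assert_allclose(predict(bundle, feats), y, atol=1e-6)

    def test_pca_dimension_and_orthonormal_basis(self, toy_features, toy_preprocessed, toy_pipeline_config):
        _, features = toy_features
        _, records = toy_preprocessed
        y = [r.scores["spontaneous"] for r in records]
        bundle = fit_pipeline(features, y, toy_pipeline_config)
        basis = bundle.pca_basis
        assert basis.shape[0] == toy_pipeline_config.pca_components
        np.testing.assert_allclose(basis @ basis.T, np.eye(basis.shape[0]), atol=1e-8)

    def test_pca_components_too_large(self, rng):
        feats = _feature_matrix(rng.normal(size=(5, 24)))
        cfg = fk.PipelineConfig.toy(pca_components=10)
        with pytest.raises(ValueError, match="pca_components"):
            fit_pipeline(feats, np.arange(5.0), cfg)

    def test_layout_mismatch_rejected(self, rng):
        cfg = fk.PipelineConfig.toy(pca_components=4)
        feats = _feature_matrix(rng.normal(size=(10, 24)))
        bundle = fit_pipeline(feats, rng.normal(size=10), cfg)
        other = _feature_matrix(rng.normal(size=(10, 48)))
        with pytest.raises(ValueError, match="layout"):
            predict(bundle, other)

    def test_duplicated_row_duplicated_prediction(self, rng):
        cfg = fk.PipelineConfig.toy(pca_components=4)
        feats = _feature_matrix(rng.normal(size=(12, 24)))
        bundle = fit_pipeline(feats, rng.normal(size=12), cfg)
        dup = _feature_matrix(np.vstack([feats.values[0], feats.values[0]]))
        preds = predict(bundle, dup)
        assert preds[0] == preds[1]

    @pytest.mark.parametrize("algorithm", ["lr", "ridgecv", "br"])
    def test_training_order_invariance(self, algorithm, rng):
        x = rng.normal(size=(20, 24))
        y = rng.normal(size=20)
        cfg = fk.PipelineConfig.toy(pca_components=6, algorithm=algorithm)
        perm = rng.permutation(20)
        b1 = fit_pipeline(_feature_matrix(x), y, cfg)
        b2 = fit_pipeline(_feature_matrix(x[perm]), y[perm], cfg)
        test = _feature_matrix(rng.normal(size=(5, 24)))
        np.testing.assert_allclose(predict(b1, test), predict(b2, test), atol=1e-8)

    def test_ridge_limit_recovers_ols(self, rng):
        x = rng.normal(size=(40, 24))
        y = x[:, 0] * 2 + rng.normal(scale=0.1, size=40)
        feats = _feature_matrix(x)
        lr = fit_pipeline(feats, y, fk.PipelineConfig.toy(pca_components=8, algorithm="lr"))
        ridge = fit_pipeline(
            feats, y,
            fk.PipelineConfig.toy(pca_components=8, algorithm="ridgecv"),
            ridge_alphas=[1e-10],
        )
        test = _feature_matrix(rng.normal(size=(6, 24)))
        np.testing.assert_allclose(predict(lr, test), predict(ridge, test), atol=1e-6)


class TestEvaluate:
    def test_perfect_and_shifted(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert evaluate(y, y) == pytest.approx((1.0, 0.0))
        r, rmse = evaluate(y + 2, y)
        assert (r, rmse) == pytest.approx((1.0, 2.0))

    def test_matches_direct_formula_oracle(self, rng):
        pred = rng.normal(size=5)
        actual = rng.normal(size=5)
        r, rmse = evaluate(pred, actual)
        dp, da = pred - pred.mean(), actual - actual.mean()
        r_oracle = np.sum(dp * da) / np.sqrt(np.sum(dp**2) * np.sum(da**2))
        rmse_oracle = np.sqrt(np.sum((pred - actual) ** 2) / 5)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert rmse == pytest.approx(rmse_oracle, abs=1e-12)

    def test_constant_actual_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            r, rmse = evaluate(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))
        assert np.isnan(r) and rmse > 0

    def test_length_validation(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(2), np.ones(2))


class TestCrossValidate:
    def test_fold_structure_and_determinism(self, toy_features, toy_preprocessed, toy_pipeline_config):
        _, features = toy_features
        _, records = toy_preprocessed
        y = [r.scores["dependent"] for r in records]
        cfg = toy_pipeline_config
        folds1 = crossvalidate(features, y, cfg)
        folds2 = crossvalidate(features, y, cfg)
        assert len(folds1) == cfg.cv_folds
        assert folds1 == folds2
        assert all(np.isfinite(rmse) for _, rmse in folds1)

    def test_too_few_samples(self, rng):
        feats = _feature_matrix(rng.normal(size=(4, 24)))
        with pytest.raises(ValueError):
            crossvalidate(feats, np.arange(4.0), fk.PipelineConfig.toy(cv_folds=5))


class TestSplitHalfReliability:
    def test_identical_halves_give_unit_reliability(self, toy_cohort, toy_pipeline_config):
        """Captures whose odd and even frames are copies must yield
        identical half-features and reliability 1 on every dimension."""
        seqs, records, _ = toy_cohort
        cfg = dataclasses.replace(toy_pipeline_config, pca_components=6)
        doubled = []
        for seq in seqs:
            out, _ = fk.preprocess_sequence(seq, cfg)
            coords = np.repeat(out.coords[: cfg.retained_frames // 2], 2, axis=0)
            doubled.append(out.replace_coords(coords))
        screening = fk.screen_corpus(doubled, cfg.top_points)
        rel = split_half_reliability(doubled, records, screening, cfg)
        for dim in DIMENSIONS:
            assert rel[dim] == pytest.approx(1.0, abs=1e-9)

    def test_half_length_and_window_arithmetic(self, toy_pipeline_config):
        cfg = toy_pipeline_config
        half = dataclasses.replace(
            cfg,
            retained_frames=cfg.retained_frames // 2,
            fft_window=cfg.fft_window // 2,
            fft_hop=cfg.fft_hop // 2,
        )
        # the halved grid preserves the window count per axis
        assert half.n_windows == cfg.n_windows
        with pytest.raises(ValueError):
            split_half_reliability(
                [], [], None, dataclasses.replace(cfg, retained_frames=cfg.retained_frames + 1,
                                                  fft_hop=1)
            )


def test_ridge_grid_is_logarithmic():
    assert len(RIDGE_ALPHAS) == 13
    np.testing.assert_allclose(np.diff(np.log10(RIDGE_ALPHAS)), 0.5)
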