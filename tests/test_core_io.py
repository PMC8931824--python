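"""Domain types, CSV round trips and GDMS item scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facekin as fk
from facekin.core_io import DIMENSIONS

BLOCK_KEY = {d: list(range(5 * i, 5 * i + 5)) for i, d in enumerate(DIMENSIONS)}


class TestLandmarkSequence:
    def test_shape_and_validation(self):
        seq = fk.LandmarkSequence("s1", np.zeros((2, 2, 3)))
        assert (seq.n_frames, seq.n_points) == (2, 2)
        with pytest.raises(ValueError):
            fk.LandmarkSequence("", np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            fk.LandmarkSequence("s1", np.zeros((0, 2, 3)))
        with pytest.raises(ValueError):
            fk.LandmarkSequence("s1", np.full((2, 2, 3), np.nan))
        with pytest.raises(ValueError):
            fk.LandmarkSequence("s1", np.zeros((2, 2, 2)))


class TestLandmarkTableIO:
    def test_round_trip(self, tmp_path, rng):
        seq = fk.LandmarkSequence("s1", rng.normal(size=(4, 3, 3)))
        path = tmp_path / "s1.csv"
        fk.write_landmark_table(seq, path)
        back = fk.read_landmark_table(path)
        assert back.subject_id == "s1"
        np.testing.assert_allclose(back.coords, seq.coords, atol=1e-9)

    def test_single_row_file(self, tmp_path):
        fk.write_landmark_table(fk.LandmarkSequence("s1", np.ones((1, 1, 3))), tmp_path / "t.csv")
        lines = (tmp_path / "t.csv").read_text().strip().splitlines()
        assert len(lines) == 2  # header + one data row

    def test_toy_grid(self, tmp_path):
        rows = ["frame,point,x,y,z"]
        for i in range(2):
            for j in range(2):
                rows.append(f"{i},{j},{i},{j},0.0")
        (tmp_path / "grid.csv").write_text("\n".join(rows))
        seq = fk.read_landmark_table(tmp_path / "grid.csv")
        assert (seq.n_frames, seq.n_points) == (2, 2)
        assert seq.coords[1, 0, 0] == 1.0

    def test_ragged_coverage_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("frame,point,x,y,z\n0,0,1,2,3\n0,1,1,2,3\n1,0,1,2,3\n")
        with pytest.raises(ValueError, match="ragged"):
            fk.read_landmark_table(tmp_path / "bad.csv")

    def test_duplicate_pair_rejected(self, tmp_path):
        (tmp_path / "dup.csv").write_text("frame,point,x,y,z\n0,0,1,2,3\n0,0,4,5,6\n")
        with pytest.raises(ValueError):
            fk.read_landmark_table(tmp_path / "dup.csv")

    def test_bad_header_and_missing_file(self, tmp_path):
        (tmp_path / "hdr.csv").write_text("frame,pt,x,y,z\n0,0,1,2,3\n")
        with pytest.raises(ValueError, match="header"):
            fk.read_landmark_table(tmp_path / "hdr.csv")
        with pytest.raises(FileNotFoundError):
            fk.read_landmark_table(tmp_path / "nope.csv")

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        (tmp_path / "nn.csv").write_text("frame,point,x,y,z\n0,0,a,2,3\n")
        with pytest.raises(ValueError, match="non-numeric"):
            fk.read_landmark_table(tmp_path / "nn.csv")


class TestScoresIO:
    def test_round_trip_and_values(self, tmp_path):
        records = [
            fk.GDMSRecord(f"s{i}", {d: 15 for d in DIMENSIONS}) for i in range(12)
        ]
        fk.write_gdms_scores(records, tmp_path / "scores.csv")
        back = fk.read_gdms_scores(tmp_path / "scores.csv")
        assert len(back) == 12
        assert all(back[0].scores[d] == 15 for d in DIMENSIONS)

    def test_missing_dimension_column_named(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["a"], "spontaneous": [10], "rational": [10],
                           "dependent": [10], "intuition": [10]})
        df.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="avoidant"):
            fk.read_gdms_scores(tmp_path / "s.csv")

    def test_duplicate_subject_rejected(self, tmp_path):
        rows = [{"subject_id": "a", **{d: 10 for d in DIMENSIONS}}] * 2
        pd.DataFrame(rows).to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            fk.read_gdms_scores(tmp_path / "s.csv")

    def test_non_integer_score_rejected(self, tmp_path):
        row = {"subject_id": "a", **{d: 10 for d in DIMENSIONS}}
        row["rational"] = 10.5
        pd.DataFrame([row]).to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="non-integer"):
            fk.read_gdms_scores(tmp_path / "s.csv")


class TestGDMSScoring:
    @pytest.mark.parametrize("value,expected", [(1, 5), (5, 25)])
    def test_extremes(self, value, expected):
        scores = fk.score_gdms_items([value] * 25, BLOCK_KEY)
        assert all(scores[d] == expected for d in DIMENSIONS)

    def test_matches_brute_force_sum(self, rng):
        for _ in range(20):
            items = rng.integers(1, 6, size=25).tolist()
            scores = fk.score_gdms_items(items, BLOCK_KEY)
            for d in DIMENSIONS:
                assert scores[d] == sum(items[i] for i in BLOCK_KEY[d])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 5), min_size=25, max_size=25), st.randoms(use_true_random=False))
    def test_invariant_to_within_block_permutation(self, items, rnd):
        base = fk.score_gdms_items(items, BLOCK_KEY)
        permuted = list(items)
        for d in DIMENSIONS:
            idx = BLOCK_KEY[d]
            vals = [items[i] for i in idx]
            rnd.shuffle(vals)
            for i, v in zip(idx, vals):
                permuted[i] = v
        assert fk.score_gdms_items(permuted, BLOCK_KEY) == base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fk.score_gdms_items([0] + [1] * 24, BLOCK_KEY)
        with pytest.raises(ValueError):
            fk.score_gdms_items([1] * 24, BLOCK_KEY)
        bad_key = dict(BLOCK_KEY)
        bad_key["spontaneous"] = [0, 1, 2, 3, 3]
        with pytest.raises(ValueError):
            fk.score_gdms_items([1] * 25, bad_key)


class TestPipelineConfig:
    def test_window_arithmetic_invariant(self):
        with pytest.raises(ValueError, match="fft_hop"):
            fk.PipelineConfig(retained_frames=2113)
        cfg = fk.PipelineConfig()
        assert cfg.n_windows == 32
        assert cfg.trim_frames == 150

    def test_file_round_trip(self, tmp_path):
        cfg = fk.PipelineConfig.toy(seed=9)
        cfg.to_file(tmp_path / "cfg.txt")
        assert fk.PipelineConfig.from_file(tmp_path / "cfg.txt") == cfg

    def test_unknown_key_and_algorithm(self, tmp_path):
        (tmp_path / "c.txt").write_text("not_a_key: 3\n")
        with pytest.raises(ValueError, match="unknown config key"):
            fk.PipelineConfig.from_file(tmp_path / "c.txt")
        with pytest.raises(ValueError, match="algorithm"):
            fk.PipelineConfig(algorithm="xgboost")
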