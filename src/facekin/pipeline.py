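"""End-to-end orchestration: cohort in, evaluation report out.

One :func:`run_pipeline` call executes preprocess → screen → extract →
model → evaluate (and split-half reliability) for a single filter width;
:func:`run_all` repeats it for W = 3 and W = 5 and writes every stage
artifact plus a :class:`RunManifest` that records row counts and the seed,
sufficient to re-run the deterministic stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    DIMENSIONS,
    GDMSRecord,
    LandmarkSequence,
    PipelineConfig,
    read_gdms_scores,
    read_landmark_table,
)
from .features import FeatureMatrix, extract_features
from .modeling import EvaluationReport, holdout_report, split_half_reliability
from .preprocess import PreprocessReport, preprocess_sequence
from .screening import ScreeningResult, screen_corpus

__all__ = [
    "RunManifest",
    "RunResult",
    "load_cohort",
    "run_pipeline",
    "run_all",
    "feature_checksum",
]

logger = logging.getLogger(__name__)


def feature_checksum(features: FeatureMatrix) -> str:
    """SHA-256 of the feature values' bytes; equal checksums mean
    bit-identical matrices."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(features.values).tobytes())
    h.update("|".join(features.subject_ids).encode())
    return h.hexdigest()


@dataclass
class RunResult:
    """Everything one single-W pipeline run computed."""

    config: PipelineConfig
    preprocess_reports: list[PreprocessReport]
    kept_ids: list[str]
    screening: ScreeningResult
    features: FeatureMatrix
    report: EvaluationReport
    reliability: dict[str, float]


@dataclass
class RunManifest:
    """Reproducibility record for one :func:`run_all` invocation."""

    config: dict
    seed: int
    data_dir: str
    output_dir: str
    version: str = __version__
    started_at: str = ""
    finished_at: str = ""
    stage_counts: dict = field(default_factory=dict)
    feature_checksums: dict = field(default_factory=dict)
    discarded: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_cohort(data_dir: str | Path) -> tuple[list[LandmarkSequence], list[GDMSRecord]]:
    """Read ``<data_dir>/landmarks/*.csv`` plus ``<data_dir>/scores.csv``.

    Only subjects present in both are returned, in scores-file order.
    """
    data_dir = Path(data_dir)
    scores_path = data_dir / "scores.csv"
    if not scores_path.exists():
        raise FileNotFoundError(f"scores file not found: {scores_path}")
    records = read_gdms_scores(scores_path)
    seqs = []
    kept_records = []
    for rec in records:
        path = data_dir / "landmarks" / f"{rec.subject_id}.csv"
        if not path.exists():
            logger.warning("no landmark file for %s; skipping", rec.subject_id)
            continue
        seqs.append(read_landmark_table(path, subject_id=rec.subject_id))
        kept_records.append(rec)
    if not seqs:
        raise FileNotFoundError(f"no landmark CSVs found under {data_dir / 'landmarks'}")
    return seqs, kept_records


def run_pipeline(
    seqs: Sequence[LandmarkSequence],
    records: Sequence[GDMSRecord],
    cfg: PipelineConfig,
    with_reliability: bool = True,
) -> RunResult:
    """Preprocess, screen, extract and evaluate one cohort at one W."""
    kept: list[LandmarkSequence] = []
    reports: list[PreprocessReport] = []
    for seq in seqs:
        out, report = preprocess_sequence(seq, cfg)
        reports.append(report)
        if out is None:
            logger.info(
                "discarding %s: %d frames after trim (< %d retained)",
                seq.subject_id, report.frames_out, cfg.retained_frames,
            )
        else:
            kept.append(out)
    kept_ids = [s.subject_id for s in kept]
    kept_records = [r for r in records if r.subject_id in set(kept_ids)]
    screening = screen_corpus(kept, cfg.top_points)
    features = extract_features(kept, screening.selected, cfg)
    report = holdout_report(features, kept_records, cfg)
    reliability = (
        split_half_reliability(kept, kept_records, screening, cfg)
        if with_reliability
        else {}
    )
    for dim, r in reliability.items():
        report.add(dim, cfg.algorithm, cfg.filter_window, "split_half_r", r)
    return RunResult(cfg, reports, kept_ids, screening, features, report, reliability)


def run_all(
    config: PipelineConfig | str | Path,
    data_dir: str | Path,
    output_dir: str | Path,
    filter_windows: Sequence[int] = (3, 5),
) -> RunManifest:
    """Run the full pipeline for each requested mean-filter width and write
    all artifacts (screening JSON, features CSV, tidy report TSV, manifest)."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_file(config)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        data_dir=str(data_dir),
        output_dir=str(output_dir),
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    seqs, records = load_cohort(data_dir)
    manifest.stage_counts["input_sequences"] = len(seqs)
    tables = []
    for w in filter_windows:
        result = run_pipeline(seqs, records, replace(cfg, filter_window=w))
        tag = f"w{w}"
        result.screening.to_json(output_dir / f"screening_{tag}.json")
        result.features.to_csv(output_dir / f"features_{tag}.csv")
        pd.DataFrame([dataclasses.asdict(r) for r in result.preprocess_reports]).to_csv(
            output_dir / f"preprocess_{tag}.tsv", sep="\t", index=False
        )
        tables.append(result.report.table)
        manifest.stage_counts[f"kept_sequences_{tag}"] = len(result.kept_ids)
        manifest.stage_counts[f"features_{tag}"] = int(result.features.values.shape[1])
        manifest.feature_checksums[tag] = feature_checksum(result.features)
        manifest.discarded.extend(
            {"subject_id": r.subject_id, "frames_in": r.frames_in, "W": w}
            for r in result.preprocess_reports
            if r.discarded
        )
    combined = EvaluationReport(pd.concat(tables, ignore_index=True))
    combined.to_tsv(output_dir / "report.tsv")
    manifest.stage_counts["report_rows"] = int(len(combined.table))
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(output_dir / "manifest.json")
    return manifest
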