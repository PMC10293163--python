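"""End-to-end orchestration: simulate -> preprocess -> features -> normative
z-scoring -> selection -> model grid -> evaluation.

``run_pipeline`` is a pure function of its :class:`~amyeeg.config.RunConfig`;
rerunning with the same configuration reproduces the report bit-identically.
A subject-id leakage audit is asserted programmatically: validation subjects
never enter augmentation, feature selection, the normative database or grid
training.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from amyeeg import evaluate as ev
from amyeeg import grid as grid_mod
from amyeeg import select as select_mod
from amyeeg import synth
from amyeeg.config import RunConfig, stage_seed
from amyeeg.features import extract_features
from amyeeg.io import write_feature_table
from amyeeg.normative import build_normative_db, standardize_table
from amyeeg.preprocess import PreprocessConfig

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Everything a full run produces, in memory."""

    config: RunConfig
    train_ids: list[str]
    validation_ids: list[str]
    feature_sets: list
    confound_set: set
    grid_result: grid_mod.GridResult
    final: grid_mod.FinalModelReport
    validation_report: dict
    topomap_tables: dict[str, pd.DataFrame]
    features_raw: pd.DataFrame  # whole-recording features, study cohort
    profiles: pd.DataFrame
    train_table: pd.DataFrame | None = None  # z-scored augmented samples
    train_labels: np.ndarray | None = None
    train_groups: np.ndarray | None = None

    def report_dict(self) -> dict:
        best = self.final.best
        return {
            "n_train_subjects": len(self.train_ids),
            "n_validation_subjects": len(self.validation_ids),
            "n_grid_cells": len(self.grid_result.cells),
            "gate_threshold": self.final.threshold,
            "best_model": {
                "feature_set": best.set_method,
                "algorithm": best.algorithm,
                "n_features": best.n_features,
                "cv_accuracy": best.cv_mean,
            },
            "validation": {
                name: rep.as_dict() for name, rep in self.validation_report.items()
            },
        }


#: Fraction of a half-recording's epochs kept as the per-sample epoch budget
#: (margin for artifact rejection).
EPOCH_BUDGET_FRACTION = 0.6


def _prep_config(cfg: RunConfig) -> PreprocessConfig:
    p = cfg.preprocess
    max_epochs = p.max_epochs
    if max_epochs is None:
        half_epochs = int((cfg.cohort.duration / 2.0) // p.epoch_length)
        max_epochs = max(2, int(EPOCH_BUDGET_FRACTION * half_epochs))
    return PreprocessConfig(
        target_fs=p.target_fs, low=p.low, high=p.high, line_freq=p.line_freq,
        epoch_length=p.epoch_length, overlap=p.overlap,
        amp_thresh=p.amp_thresh, var_mult=p.var_mult, ocular_mode=p.ocular_mode,
        max_epochs=max_epochs,
    )


def _cohort_spec(cfg: RunConfig) -> synth.CohortSpec:
    c = cfg.cohort
    return synth.CohortSpec(
        n_scd_pos=c.n_scd_pos, n_scd_neg=c.n_scd_neg,
        n_mci_pos=c.n_mci_pos, n_mci_neg=c.n_mci_neg,
        delta_theta=c.delta_theta, delta_beta2=c.delta_beta2,
        mci_multiplier=c.mci_multiplier,
        blink_rate_per_min=c.blink_rate_per_min,
        emg_rate_per_min=c.emg_rate_per_min,
        line_noise_uv=c.line_noise_uv, line_freq=c.line_freq,
        duration=c.duration, fs=c.fs,
        seed=stage_seed(cfg.master_seed, "cohort"),
    )


def extract_table(recordings, prep: PreprocessConfig) -> pd.DataFrame:
    """Whole-recording feature vectors for an iterable of recordings."""
    return pd.DataFrame([extract_features(r, prep) for r in recordings])


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; optionally write reports under ``out_dir``.

    Recordings are synthesized and reduced to feature vectors one at a time,
    so memory stays flat in the cohort size.
    """
    prep = _prep_config(cfg)
    spec = _cohort_spec(cfg)

    logger.info("study cohort: synthesizing %d subjects and extracting features",
                spec.n_total)
    study_profiles: list = []
    whole_rows: list[pd.Series] = []
    half_rows: dict[str, tuple[pd.Series, pd.Series]] = {}
    for rec in synth.iter_study_cohort(spec):
        study_profiles.append(rec.profile)
        whole_rows.append(extract_features(rec, prep))
        if rec.profile.amyloid == "POS":
            first, second = grid_mod.split_halves(rec)
            half_rows[rec.subject_id] = (
                extract_features(first, prep), extract_features(second, prep)
            )
    study_features = pd.DataFrame(whole_rows)
    profiles = pd.DataFrame(
        {
            p.subject_id: {"age": p.age, "sex": p.sex,
                           "diagnosis": p.diagnosis, "amyloid": p.amyloid}
            for p in study_profiles
        }
    ).T

    logger.info("normative cohort: synthesizing and extracting features")
    norm_rows: list[pd.Series] = []
    norm_meta: dict[str, dict] = {}
    for rec in synth.iter_normative_cohort(
        cfg.normative.n_per_stratum,
        age_bins=cfg.normative.age_bins,
        seed=stage_seed(cfg.master_seed, "normative"),
        duration=cfg.cohort.duration, fs=cfg.cohort.fs,
        blink_rate_per_min=cfg.cohort.blink_rate_per_min,
        emg_rate_per_min=cfg.cohort.emg_rate_per_min,
        line_noise_uv=cfg.cohort.line_noise_uv, line_freq=cfg.cohort.line_freq,
    ):
        norm_rows.append(extract_features(rec, prep))
        p = rec.profile
        norm_meta[p.subject_id] = {"age": p.age, "sex": p.sex}
    norm_features = pd.DataFrame(norm_rows)
    norm_profiles = pd.DataFrame.from_dict(norm_meta, orient="index")

    train_ids, val_ids = synth.split_ids(
        study_profiles, cfg.split.as_counts(), seed=stage_seed(cfg.master_seed, "split")
    )
    assert not set(train_ids) & set(val_ids), "train/validation subject overlap"

    db = build_normative_db(norm_features, norm_profiles, cfg.normative.age_bins)

    # Positive-class augmentation: training positives contribute their two
    # half-recording feature vectors instead of the whole-recording one.
    amyloid_of = profiles["amyloid"]
    samples = []
    for sid in train_ids:
        if amyloid_of[sid] == "POS":
            first, second = half_rows[sid]
            samples.append(grid_mod.AugmentedSample(sid, 1, first, 1))
            samples.append(grid_mod.AugmentedSample(sid, 2, second, 1))
        else:
            samples.append(
                grid_mod.AugmentedSample(sid, 0, study_features.loc[sid], 0)
            )
    X_aug, y_aug, groups = grid_mod.samples_to_table(samples)
    assert not set(groups) & set(val_ids), "validation subject leaked into augmentation"

    # Normative z-scoring of training samples and validation subjects.
    aug_profiles = pd.DataFrame(
        {
            "age": [profiles.loc[g, "age"] for g in groups],
            "sex": [profiles.loc[g, "sex"] for g in groups],
        },
        index=X_aug.index,
    )
    Z_aug = standardize_table(X_aug, aug_profiles, db)
    Z_val = standardize_table(
        study_features.loc[val_ids], profiles.loc[val_ids], db
    )
    y_val = (profiles.loc[val_ids, "amyloid"] == "POS").to_numpy().astype(int)

    logger.info("feature selection (6 methods + confound exclusion)")
    sel_seed = stage_seed(cfg.master_seed, "selection")
    amyloid_sets = select_mod.select_all(
        Z_aug, y_aug, alpha=cfg.selection.alpha, k=cfg.selection.k, seed=sel_seed
    )
    if cfg.selection.exclude_confounds:
        diag_labels = np.array([profiles.loc[g, "diagnosis"] for g in groups])
        feature_sets, confounds = select_mod.exclude_cognitive_confounds(
            amyloid_sets, Z_aug, diag_labels,
            alpha=cfg.selection.alpha, k=cfg.selection.k, seed=sel_seed,
        )
    else:
        feature_sets, confounds = amyloid_sets, set()

    logger.info("training the %d x %d model grid", len(feature_sets), len(grid_mod.ALGORITHM_NAMES))
    grid_seed = stage_seed(cfg.master_seed, "grid")
    gr = grid_mod.run_grid(
        feature_sets, grid_mod.ALGORITHM_NAMES, Z_aug, y_aug, groups,
        folds=cfg.grid.folds, seed=grid_seed,
    )
    final = grid_mod.gate_and_select(
        gr, feature_sets, Z_aug, y_aug, Z_val, y_val,
        threshold=cfg.grid.gate_threshold, seed=grid_seed,
    )

    best = final.best
    report = ev.subgroup_report(
        y_val, best.predictions,
        profiles.loc[val_ids, "diagnosis"].to_numpy(),
        scores=best.scores,
    )

    topomaps = {
        g: ev.group_topomap_table(study_features, profiles, g)
        for g in ev.GROUPINGS
    }

    result = RunResult(
        config=cfg, train_ids=train_ids, validation_ids=val_ids,
        feature_sets=feature_sets, confound_set=confounds,
        grid_result=gr, final=final, validation_report=report,
        topomap_tables=topomaps, features_raw=study_features, profiles=profiles,
        train_table=Z_aug, train_labels=y_aug, train_groups=groups,
    )
    if out_dir is not None:
        _write_outputs(result, Z_aug, aug_profiles, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: RunResult, Z_aug: pd.DataFrame,
                   aug_profiles: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    split = {sid: "train" for sid in result.train_ids}
    split.update({sid: "validation" for sid in result.validation_ids})
    features_path = out_dir / "features.csv"
    write_feature_table(result.features_raw, result.profiles, features_path, split=split)

    sets_payload = [
        {
            "method": fs.method, "rule": fs.rule, "rule_value": fs.rule_value,
            "names": fs.names, "scores": fs.scores,
        }
        for fs in result.feature_sets
    ]
    (out_dir / "feature_sets.json").write_text(json.dumps(
        {"sets": sets_payload, "confound_set": sorted(result.confound_set)}, indent=1
    ))

    grid_path = out_dir / "grid.csv"
    result.grid_result.as_frame().to_csv(grid_path, index=False)

    for name, table in result.topomap_tables.items():
        table.to_csv(out_dir / f"topomap_{name}.csv", index=False)

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(result.report_dict(), indent=1, sort_keys=True))

    manifest = {
        "schema_version": cfg.schema_version,
        "master_seed": cfg.master_seed,
        "config": cfg.model_dump(),
        "fold_map": result.grid_result.fold_map,
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out_dir.glob("*"))
            if p.name != "manifest.json"
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
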