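"""End-to-end experiment orchestration: simulate -> train -> predict -> evaluate.

Each stage logs its seed, writes its artifacts under the output root and
records them in ``experiment_manifest.json``, so a finished directory is
self-describing and re-runnable from the config alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .architectures import ModelSpec, save_checkpoint
from .config import RunConfig
from .inference import predict_case
from .io import write_volume
from .metrics import evaluate_case, records_to_frame, summarize
from .phantom import (CohortManifest, GridSpec, PhantomGeometry, SpectralModel,
                      generate_cohort)
from .training import TrainConfig, make_folds, train_fold, write_training_log

logger = logging.getLogger("spectralseg.experiment")

_TUPLE_GEOMETRY_FIELDS = ("head_semi_axes", "ventricle_semi_axes")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, seed: int):
    logger.info("stage=%s seed=%d wall=%s", name, seed,
                time.strftime("%Y-%m-%dT%H:%M:%S"))


def build_geometry(overrides: dict) -> PhantomGeometry:
    fixed = {k: tuple(v) if k in _TUPLE_GEOMETRY_FIELDS and isinstance(v, list)
             else v for k, v in overrides.items()}
    return PhantomGeometry(**fixed)


def build_spectral(overrides: dict) -> SpectralModel:
    kwargs = {}
    if "hu_table" in overrides:
        kwargs["hu_table"] = {int(lv): {int(c): float(hu) for c, hu in row.items()}
                              for lv, row in overrides["hu_table"].items()}
    if "noise_sd" in overrides:
        kwargs["noise_sd"] = {int(lv): float(sd)
                              for lv, sd in overrides["noise_sd"].items()}
    return SpectralModel(**kwargs)


def split_test_cases(case_ids: list[str], test_fraction: float,
                     seed: int) -> tuple[list[str], list[str]]:
    """Deterministic train/test split (test size rounded, at least 1)."""
    ids = sorted(case_ids)
    n_test = max(1, round(len(ids) * test_fraction))
    if n_test >= len(ids):
        raise ValueError("test split would consume every case")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E57]))
    order = [ids[i] for i in rng.permutation(len(ids))]
    return sorted(order[n_test:]), sorted(order[:n_test])


def run_experiment(config: RunConfig, reuse_cohort: bool = True) -> dict:
    """Run the full pipeline described by ``config``; returns the report.

    The report holds the artifact paths, the train/test split, fold
    assignment, per-epoch training losses and the per-case metric records.
    """
    root = Path(config.out_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest_entry: dict = {"config": config.to_dict(), "artifacts": {}}

    # -- simulate ------------------------------------------------------------
    _stage("simulate", config.seed)
    cohort_dir = root / "cohort"
    try:
        if reuse_cohort and (cohort_dir / "manifest.json").exists():
            cohort = CohortManifest.load(cohort_dir / "manifest.json")
            if len(cohort.case_ids) != config.phantom.n_cases:
                raise ValueError("existing cohort size disagrees with config")
        else:
            cohort = generate_cohort(
                config.phantom.n_cases, cohort_dir,
                geometry=build_geometry(config.phantom.geometry),
                spectral=build_spectral(config.phantom.spectral),
                grid=GridSpec(tuple(config.phantom.grid_shape),
                              tuple(config.phantom.grid_spacing)),
                seed=config.seed)
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    manifest_entry["artifacts"]["cohort"] = str(cohort_dir / "manifest.json")

    # -- folds ---------------------------------------------------------------
    _stage("folds", config.seed)
    try:
        train_ids, test_ids = split_test_cases(
            cohort.case_ids, config.evaluation.test_fraction, config.seed)
        folds = make_folds(train_ids, n_folds=config.training.n_folds,
                           seed=config.seed)
        folds.save(root / "folds.json")
    except Exception as exc:
        raise StageError("folds", exc) from exc
    manifest_entry["split"] = {"train": train_ids, "test": test_ids}
    manifest_entry["artifacts"]["folds"] = str(root / "folds.json")

    # -- train ---------------------------------------------------------------
    _stage("train", config.seed)
    spec = ModelSpec(backbone=config.model.backbone, variant=config.model.variant,
                     widths=config.model.widths,
                     k_slices=config.training.k_slices)
    tconf = TrainConfig(epochs=config.training.epochs,
                        batch_size=config.training.batch_size,
                        learning_rate=config.training.learning_rate,
                        seed=config.seed,
                        baseline_level=config.training.baseline_level,
                        k_slices=config.training.k_slices,
                        window=tuple(config.training.window),
                        levels=tuple(config.training.levels))
    ckpt_dir = root / "checkpoints"
    models, logs = [], []
    try:
        cases = {cid: cohort.load_case(cid) for cid in cohort.case_ids}
        for k in range(config.training.n_folds):
            model, log = train_fold(cases, folds, k, spec, tconf)
            save_checkpoint(model, ckpt_dir / f"fold_{k}.npz")
            write_training_log(log, ckpt_dir / f"fold_{k}_loss.csv")
            models.append(model)
            logs.append(log)
    except Exception as exc:
        raise StageError("train", exc) from exc
    manifest_entry["artifacts"]["checkpoints"] = str(ckpt_dir)

    # -- predict -------------------------------------------------------------
    _stage("predict", config.seed)
    pred_dir = root / "predictions"
    pred_dir.mkdir(exist_ok=True)
    results = {}
    try:
        for cid in test_ids:
            stack, _ = cases[cid]
            res = predict_case(models, stack, case_id=cid,
                               window=tuple(config.training.window),
                               baseline_level=config.training.baseline_level,
                               checkpoints=[f"fold_{k}.npz"
                                            for k in range(len(models))])
            write_volume(res.labels.data, res.labels.spacing,
                         pred_dir / f"{cid}_labels.nii.gz")
            results[cid] = res
    except Exception as exc:
        raise StageError("predict", exc) from exc
    manifest_entry["artifacts"]["predictions"] = str(pred_dir)

    # -- evaluate ------------------------------------------------------------
    _stage("evaluate", config.seed)
    report_dir = root / "report"
    report_dir.mkdir(exist_ok=True)
    try:
        records = []
        for cid in test_ids:
            _, truth = cases[cid]
            records.extend(evaluate_case(results[cid].labels, truth, case_id=cid))
        frame = records_to_frame(records)
        frame.to_csv(report_dir / "per_case_metrics.csv", index=False)
        summary = summarize(records)
        summary.to_csv(report_dir / "per_class_summary.csv", index=False)
    except Exception as exc:
        raise StageError("evaluate", exc) from exc
    manifest_entry["artifacts"]["report"] = str(report_dir)

    report = {
        "split": manifest_entry["split"],
        "folds": folds.assignment,
        "training_logs": logs,
        "records": [vars(r).copy() for r in records],
        "summary": summary.to_dict(orient="records"),
        "artifacts": manifest_entry["artifacts"],
    }
    (root / "experiment_manifest.json").write_text(json.dumps(manifest_entry, indent=2))
    return report
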