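"""End-to-end pipeline: synth -> preprocess -> train -> evaluate -> spectra -> correlate.

One YAML-style config dict drives every stage; the global seed fans out to
per-stage seeds by fixed offsets (synth +0, folds/training +10000, evaluate
bootstrap +20000, spectra bootstrap +30000).  Stage outputs are cached in
the run directory and a stage is skipped when its artifacts already exist,
so deleting one output file re-executes only the stages downstream of it.
Every numeric result file carries the config hash and seed in a header.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import spectra as sp
from . import correlate as co
from .augment import AugmentConfig
from .core import SegmentSet
from .model import DEFAULT_BLOCKS, SMOKE_BLOCKS, ModelSpec
from .preprocess import ArtifactConfig, preprocess_recording
from .synth import CohortSpec, generate_cohort, read_metadata, write_cohort
from .train import TrainConfig, dataset_from_segments, train_ensemble

log = logging.getLogger("placebo_eeg")

#: Fixed seed offsets per stage.
SEED_OFFSETS = {"synth": 0, "train": 10_000, "evaluate": 20_000, "spectra": 30_000}


DEFAULT_CONFIG: dict = {
    "profile": "smoke",
    "seed": 0,
    "synth": {
        "n_subjects": 20,
        "responder_rate": 0.4,
        "duration_s": 24.0,
        "effect_theta": -2.0,
        "effect_beta_low": -2.0,
        "sex_effect": -0.5,
        "age_slope": -1.0,
        "artifact_rates": {},  # rule -> probability; empty = clean cohort
    },
    "preprocess": {"ocular_method": "regression"},
    "augment": {"noise_sd_max": 0.2, "amp_max": 1.2, "scale_min": 0.5},
    "train": {
        "n_models": 1,
        "max_epochs": 32,
        "batch_size": 32,
        "baseline_lr": 1e-2,
        "finetune_lr": 1e-2,
        "weight_decay": 0.01,
        "early_stop_epochs": 20,
        "rotations": None,  # None = all k rotations
    },
    "evaluate": {"n_boot": 200, "threshold": 0.5},
    "spectra": {"n_boot": 200, "predictors": "headline"},  # or list of [channel, band]
    "correlate": {"family": ["age_years", "extraversion", "reaction_time"]},
}

#: The six strongest predictors reported for the planted structure.
HEADLINE_PREDICTORS = [
    ("F8", "theta"), ("Cz", "theta"), ("Fz", "theta"), ("C3", "theta"),
    ("F4", "beta_low"), ("F3", "beta_low"),
]


def merge_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                _merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        _merge(cfg, overrides)
    if cfg["profile"] == "paper-scale":
        _merge(cfg, {
            "synth": {"n_subjects": 141, "duration_s": 120.0},
            "train": {"n_models": 20, "max_epochs": 100, "batch_size": 512,
                      "baseline_lr": None, "finetune_lr": None},
            "evaluate": {"n_boot": 1000},
            "spectra": {"n_boot": 1000},
        })
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _header(cfg: dict) -> str:
    return f"# config_hash={config_hash(cfg)} seed={cfg['seed']}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _write_json(obj: dict, path: Path, cfg: dict) -> None:
    payload = {"config_hash": config_hash(cfg), "seed": cfg["seed"]} | obj
    path.write_text(json.dumps(payload, indent=2))


def save_segments(segset: SegmentSet, path: Path, cfg: dict) -> None:
    np.savez_compressed(path, data=segset.data, kept_mask=segset.kept_mask)
    sidecar = pd.DataFrame(segset.index)
    sidecar["kept"] = segset.kept_mask
    sidecar["reject_reason"] = [",".join(r) for r in segset.reject_reason]
    _write_tsv(sidecar, path.with_suffix(".tsv"), cfg)


def load_segments(path: Path) -> SegmentSet:
    with np.load(path) as data:
        arr, kept = data["data"], data["kept_mask"]
    sidecar = read_tsv(path.with_suffix(".tsv"))
    index = sidecar[["subject_id", "session_id", "eye_state", "start_s"]].to_dict("records")
    reasons = [
        tuple(r.split(",")) if isinstance(r, str) and r else ()
        for r in sidecar["reject_reason"].fillna("")
    ]
    return SegmentSet(data=arr, index=index, kept_mask=kept, reject_reason=reasons)


def _model_spec(cfg: dict) -> ModelSpec:
    blocks = SMOKE_BLOCKS if cfg["profile"] == "smoke" else DEFAULT_BLOCKS
    return ModelSpec(blocks=blocks, init_seed=cfg["seed"])


def run_pipeline(cfg: dict | None = None, out_dir: str | Path = "runs/pipeline") -> Path:
    """Execute all stages into ``out_dir``; deterministic given the seed."""
    cfg = merge_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    seed = int(cfg["seed"])

    # --- synth
    meta_csv = out / "cohort" / "metadata.csv"
    if not meta_csv.exists():
        log.info("stage synth: generating cohort")
        spec = CohortSpec(seed=seed + SEED_OFFSETS["synth"], **cfg["synth"])
        recordings, subjects = generate_cohort(spec)
        write_cohort(recordings, subjects, out / "cohort")
    subjects = read_metadata(meta_csv)
    meta_frame = pd.read_csv(meta_csv)

    # --- preprocess
    seg_path = out / "segments.npz"
    if not seg_path.exists():
        log.info("stage preprocess: filtering, artifact rules, segmentation")
        from .edf import read_edf

        parts = []
        for edf_file in sorted((out / "cohort").glob("*.edf")):
            rec = read_edf(edf_file)
            parts.append(preprocess_recording(
                rec, ocular_method=cfg["preprocess"]["ocular_method"],
                cfg=ArtifactConfig(),
            ))
        save_segments(SegmentSet.concatenate(parts), seg_path, cfg)
    segset = load_segments(seg_path)

    # --- train
    preds_path = out / "preds.tsv"
    if not preds_path.exists():
        log.info("stage train: two-stage ensemble")
        tr = cfg["train"]
        aug = AugmentConfig(**cfg["augment"])
        preds, models = train_ensemble(
            dataset_from_segments(segset), subjects,
            n_models=int(tr["n_models"]), base_seed=seed + SEED_OFFSETS["train"],
            baseline_cfg=TrainConfig(stage="baseline", lr=tr["baseline_lr"],
                                     weight_decay=float(tr.get("weight_decay", 0.1)),
                                     batch_size=int(tr["batch_size"]),
                                     max_epochs=int(tr["max_epochs"]),
                                     early_stop_epochs=int(tr["early_stop_epochs"]),
                                     augment=aug),
            finetune_cfg=TrainConfig(stage="finetune", lr=tr["finetune_lr"],
                                     weight_decay=float(tr.get("weight_decay", 0.1)),
                                     batch_size=int(tr["batch_size"]),
                                     max_epochs=int(tr["max_epochs"]),
                                     early_stop_epochs=int(tr["early_stop_epochs"]),
                                     augment=aug),
            spec=_model_spec(cfg),
            rotations=tr.get("rotations"),
        )
        _write_tsv(preds, preds_path, cfg)
        ckpt_dir = out / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        for m, (model, folds) in enumerate(models):
            model.save(ckpt_dir / f"model_{m:02d}.npz")
            (ckpt_dir / f"folds_{m:02d}.json").write_text(json.dumps(folds.assignment, indent=2))
    preds = read_tsv(preds_path)

    labels = {s.subject_id: int(s.remission) for s in subjects if s.arm == "placebo"}
    labels = {k: v for k, v in labels.items() if k in set(preds["subject_id"])}

    # --- evaluate
    metrics_path = out / "metrics.json"
    if not metrics_path.exists():
        log.info("stage evaluate: bootstrap ensemble metrics")
        report = ev.bootstrap_metrics(
            preds, labels, n_boot=int(cfg["evaluate"]["n_boot"]),
            threshold=float(cfg["evaluate"]["threshold"]),
            seed=seed + SEED_OFFSETS["evaluate"],
        )
        point = ev.compute_metrics(ev.aggregate_subject_scores(preds), labels)
        _write_json({"bootstrap": report.to_dict(), "point": point}, metrics_path, cfg)

    # --- spectra
    spectra_path = out / "spectra.tsv"
    if not spectra_path.exists():
        log.info("stage spectra: band-power bootstrap regression")
        session_scores = (
            preds.groupby(["subject_id", "session_id"], as_index=False)["probability"]
            .mean().rename(columns={"probability": "score"})
        )
        powers = sp.band_power_segments(segset)
        predictors = cfg["spectra"]["predictors"]
        if predictors == "headline":
            predictors = HEADLINE_PREDICTORS
        predictors = [tuple(p) for p in predictors]
        results = sp.bootstrap_regression(
            session_scores, powers, predictors, meta_frame,
            n_boot=int(cfg["spectra"]["n_boot"]), seed=seed + SEED_OFFSETS["spectra"],
        )
        _write_tsv(pd.DataFrame([r.to_row() for r in results]), spectra_path, cfg)

    # --- correlate
    corr_path = out / "correlations.tsv"
    if not corr_path.exists():
        log.info("stage correlate: Holm-corrected covariate screening")
        scores = ev.aggregate_subject_scores(preds)
        results = co.correlate_covariates(scores, meta_frame, cfg["correlate"]["family"])
        _write_tsv(co.results_table(results), corr_path, cfg)

    return out
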