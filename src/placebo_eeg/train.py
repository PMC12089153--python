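"""Two-stage training under subject-grouped 5-fold cross-validation.

Stage one ("baseline") learns remission (depression-scale endpoint <= 7)
from all treatment arms; stage two ("finetune") restarts from the baseline
checkpoint, restricts the data to the placebo arm, freezes blocks L1-L7 and
updates only L8 and the classifier head, specializing the late features to
placebo response.  Folds are assigned per subject — every segment and both
eye-state sessions of a subject share one fold — so train, validation and
test subject sets never intersect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, augment_batch
from .core import SegmentSet
from .model import Model, ModelSpec
from .synth import SubjectRecord

__all__ = [
    "FoldSplit", "TrainConfig", "SegmentDataset", "make_folds",
    "train_baseline", "finetune_placebo", "train_ensemble", "dataset_from_segments",
]

K_FOLDS = 5
#: Blocks kept frozen during fine-tuning: everything below L8 and the head.
FINETUNE_FROZEN: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5", "L6", "L7")


@dataclass(frozen=True)
class FoldSplit:
    """Subject -> fold assignment with the rotation convention.

    For iteration ``i`` of the rotation: test = fold ``i``, validation =
    fold ``(i+1) mod k``, train = the remaining ``k-2`` folds.
    """

    assignment: dict
    k: int = K_FOLDS

    def roles(self, iteration: int) -> tuple[set, set, set]:
        test_fold = iteration % self.k
        val_fold = (iteration + 1) % self.k
        train, val, test = set(), set(), set()
        for subj, fold in self.assignment.items():
            (test if fold == test_fold else val if fold == val_fold else train).add(subj)
        if train & val or train & test or val & test:  # pragma: no cover - hard guard
            raise AssertionError("subject leakage across train/validation/test")
        return train, val, test


def make_folds(
    subjects: Sequence[SubjectRecord] | Sequence[str],
    k: int = K_FOLDS,
    seed: int = 0,
    stratify_by: Optional[dict] = None,
) -> FoldSplit:
    """Deterministic near-equal subject partition (fold sizes differ by <= 1).

    With ``stratify_by`` (subject -> label), subjects are dealt round-robin
    within a label-sorted shuffle so class balance is approximately even
    across folds.
    """
    ids = [s.subject_id if isinstance(s, SubjectRecord) else str(s) for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    if stratify_by is not None:
        order.sort(key=lambda s: str(stratify_by.get(s)))  # stable: keeps shuffle within class
    assignment = {subj: i % k for i, subj in enumerate(order)}
    return FoldSplit(assignment=assignment, k=k)


@dataclass
class TrainConfig:
    """Optimization settings for one training stage.

    ``lr=None`` selects the stage default (3e-5 baseline, 1e-4 finetune).
    Early stopping halts after ``early_stop_epochs`` epochs without
    validation-loss improvement; the plateau scheduler halves the learning
    rate after ``patience`` non-improving epochs.
    """

    stage: str = "baseline"  # or "finetune"
    lr: Optional[float] = None
    weight_decay: float = 0.1
    batch_size: int = 512
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    early_stop_epochs: int = 20
    max_epochs: int = 100
    seed: int = 0
    pos_weight: float = 1.0
    restarts: int = 1  # extra attempts if validation never beats the trivial predictor
    augment: Optional[AugmentConfig] = field(default_factory=AugmentConfig)
    frozen_layers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in ("baseline", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "baseline" and self.frozen_layers:
            raise ValueError("frozen_layers is only meaningful in the finetune stage")
        if self.stage == "finetune" and not self.frozen_layers:
            self.frozen_layers = FINETUNE_FROZEN
        if self.lr is None:
            self.lr = 3e-5 if self.stage == "baseline" else 1e-4


@dataclass
class SegmentDataset:
    """Kept segments flattened across recordings, with provenance arrays."""

    X: np.ndarray  # [N, 19, 2000] float32
    subject_ids: np.ndarray
    session_ids: np.ndarray
    eye_states: np.ndarray
    start_s: np.ndarray

    def __len__(self) -> int:
        return len(self.X)

    def subset_subjects(self, subjects: set) -> "SegmentDataset":
        m = np.isin(self.subject_ids, list(subjects))
        return SegmentDataset(self.X[m], self.subject_ids[m], self.session_ids[m],
                              self.eye_states[m], self.start_s[m])


def dataset_from_segments(segset: SegmentSet) -> SegmentDataset:
    idx = segset.kept_index()
    return SegmentDataset(
        X=segset.kept_data().astype(np.float32),
        subject_ids=np.array([i["subject_id"] for i in idx]),
        session_ids=np.array([i["session_id"] for i in idx]),
        eye_states=np.array([i["eye_state"] for i in idx]),
        start_s=np.array([i["start_s"] for i in idx], dtype=float),
    )


def _segment_labels(ds: SegmentDataset, labels: dict) -> np.ndarray:
    missing = sorted(set(ds.subject_ids) - set(labels))
    if missing:
        raise ValueError(f"labels missing for subjects: {', '.join(missing[:5])}")
    return np.array([float(labels[s]) for s in ds.subject_ids])


def _trivial_val_loss(y_train: np.ndarray, y_val: np.ndarray) -> float:
    """Validation loss of the best constant predictor (train prevalence)."""
    p = float(np.clip(y_train.mean(), 1e-6, 1 - 1e-6))
    logit = np.log(p / (1 - p))
    loss, _ = nn.bce_with_logits(np.full(len(y_val), logit), y_val)
    return loss


def _run_training(
    model_factory,
    train_ds: SegmentDataset,
    y_train: np.ndarray,
    val_ds: SegmentDataset,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> tuple[Model, list[dict]]:
    """Train with validation-selected restarts.

    Optimization of this family of models from random init is bimodal: a
    run either escapes the constant-prediction plateau or never does.  A
    run whose best validation loss fails to beat the trivial constant
    predictor is therefore retried (up to ``cfg.restarts`` extra attempts,
    each with a shifted seed); the best attempt by validation loss wins.
    """
    trivial = _trivial_val_loss(y_train, y_val)
    best: tuple[float, Model, list[dict]] | None = None
    for attempt in range(cfg.restarts + 1):
        seed_a = cfg.seed + 7919 * attempt
        model = model_factory(seed_a)
        val_loss, history = _run_training_once(model, train_ds, y_train, val_ds, y_val,
                                               cfg, seed_a)
        if best is None or val_loss < best[0]:
            best = (val_loss, model, history)
        if val_loss < 0.95 * trivial:
            break
    _, model, history = best
    model.eval_mode()
    return model, history


def _run_training_once(
    model: Model,
    train_ds: SegmentDataset,
    y_train: np.ndarray,
    val_ds: SegmentDataset,
    y_val: np.ndarray,
    cfg: TrainConfig,
    seed: int,
) -> tuple[float, list[dict]]:
    """One epoch loop; loads the best-validation state and returns its loss."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels are single-class; the loss is degenerate")
    rng = np.random.default_rng(seed)
    frozen_blocks = set(cfg.frozen_layers)
    frozen_params = {
        name for name in model.named_params() if name.split(".")[0] in frozen_blocks
    }
    opt = nn.AdamW(model.named_params(), lr=cfg.lr, weight_decay=cfg.weight_decay,
                   frozen=frozen_params)
    # when the frozen set is a prefix L1..Lk, backprop can stop after block k+1
    stop_block = None
    prefix = [f"L{i}" for i in range(1, 9)]
    if frozen_blocks and all(b in prefix for b in frozen_blocks):
        k = max(int(b[1:]) for b in frozen_blocks)
        if set(frozen_blocks) == set(prefix[:k]) and k < 8:
            stop_block = f"L{k + 1}"
    sched = nn.ReduceLROnPlateau(opt, patience=cfg.plateau_patience, factor=cfg.plateau_factor)

    # the incoming state (for fine-tuning: the baseline checkpoint) competes
    # as a candidate, so training can never end worse than it started on the
    # validation loss
    best_state = model.state_dict()
    init_logits = model.predict_logits_batched(val_ds.X, cfg.batch_size)
    best_val, _ = nn.bce_with_logits(init_logits, y_val)
    best_epoch = -1
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        model.train_mode(frozen_blocks=frozen_blocks)
        perm = rng.permutation(len(train_ds))
        losses = []
        for i0 in range(0, len(perm), cfg.batch_size):
            sel = perm[i0 : i0 + cfg.batch_size]
            if len(sel) < 2:
                continue  # batch norm needs more than one sample
            xb = train_ds.X[sel]
            if cfg.augment is not None:
                xb = augment_batch(xb, rng, cfg.augment).astype(np.float32)
            logits = model.forward(xb)
            loss, dlogits = nn.bce_with_logits(logits, y_train[sel], cfg.pos_weight)
            model.backward(dlogits, stop_block=stop_block)
            opt.step(model.grads())
            losses.append(loss)

        val_logits = model.predict_logits_batched(val_ds.X, cfg.batch_size)
        val_loss, _ = nn.bce_with_logits(val_logits, y_val)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "val_loss": float(val_loss),
            "lr": opt.lr,
        })
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.early_stop_epochs:
            break
        sched.step(val_loss)

    model.load_state_dict(best_state)
    return best_val, history


def train_baseline(
    ds: SegmentDataset,
    labels: dict,
    folds: FoldSplit,
    cfg: TrainConfig,
    spec: ModelSpec | None = None,
    iteration: int = 0,
) -> tuple[Model, list[dict]]:
    """Stage one: remission classifier over all arms for one rotation."""
    if cfg.stage != "baseline":
        raise ValueError("train_baseline requires a baseline-stage config")
    train_subj, val_subj, _ = folds.roles(iteration)
    train_ds = ds.subset_subjects(train_subj)
    val_ds = ds.subset_subjects(val_subj)
    base_spec = spec or ModelSpec(init_seed=cfg.seed)
    model, history = _run_training(
        lambda s: Model(replace(base_spec, init_seed=s)),
        train_ds, _segment_labels(train_ds, labels),
        val_ds, _segment_labels(val_ds, labels), cfg,
    )
    return model, history


def finetune_placebo(
    baseline: Model,
    ds: SegmentDataset,
    labels: dict,
    folds: FoldSplit,
    cfg: TrainConfig,
    arms: dict,
    iteration: int = 0,
) -> tuple[Model, list[dict]]:
    """Stage two: placebo-responder fine-tune with L1-L7 frozen.

    ``ds`` must already be restricted to placebo-arm subjects (checked
    against ``arms``); the baseline model's weights are the starting point
    and everything outside L8 + head stays bit-identical.
    """
    if cfg.stage != "finetune":
        raise ValueError("finetune_placebo requires a finetune-stage config")
    non_placebo = sorted({s for s in ds.subject_ids if arms.get(s) != "placebo"})
    if non_placebo:
        raise ValueError(f"non-placebo subjects in fine-tune data: {', '.join(non_placebo[:5])}")
    train_subj, val_subj, _ = folds.roles(iteration)
    train_ds = ds.subset_subjects(train_subj)
    val_ds = ds.subset_subjects(val_subj)
    baseline_state = baseline.state_dict()

    def from_baseline(_seed: int) -> Model:
        m = Model(baseline.spec)
        m.load_state_dict(baseline_state)
        return m

    model, history = _run_training(
        from_baseline, train_ds, _segment_labels(train_ds, labels),
        val_ds, _segment_labels(val_ds, labels), cfg,
    )
    return model, history


def predict_table(model: Model, ds: SegmentDataset, model_id: int = 0,
                  batch_size: int = 512) -> pd.DataFrame:
    """Per-segment logits/probabilities as PredictionTable rows."""
    logits = model.predict_logits_batched(ds.X, batch_size)
    return pd.DataFrame({
        "model_id": model_id,
        "subject_id": ds.subject_ids,
        "session_id": ds.session_ids,
        "eye_state": ds.eye_states,
        "segment_idx": ds.start_s.astype(int),
        "logit": logits,
        "probability": nn.sigmoid(logits),
    })


def train_ensemble(
    ds: SegmentDataset,
    meta: Sequence[SubjectRecord],
    n_models: int = 20,
    base_seed: int = 0,
    baseline_cfg: TrainConfig | None = None,
    finetune_cfg: TrainConfig | None = None,
    spec: ModelSpec | None = None,
    k: int = K_FOLDS,
    rotations: int | None = None,
) -> tuple[pd.DataFrame, list[tuple[Model, FoldSplit]]]:
    """Train ``n_models`` two-stage models, each with its own seed and split.

    Every model runs ``rotations`` of the k-rotation (all k by default, so
    its test predictions cover each subject exactly once); the pooled table
    is the substrate for the bootstrap-ensemble evaluation.  Test
    predictions are emitted for placebo-arm subjects (the population the
    fine-tuned model is about).
    """
    remission = {s.subject_id: int(s.remission) for s in meta}
    arms = {s.subject_id: s.arm for s in meta}
    placebo_subjects = {s.subject_id for s in meta if s.arm == "placebo"}
    tables, models = [], []
    for m in range(n_models):
        seed_m = int(base_seed) + 1000 * m
        b_cfg = replace(baseline_cfg or TrainConfig(stage="baseline"), seed=seed_m)
        f_cfg = replace(finetune_cfg or TrainConfig(stage="finetune"), seed=seed_m + 1,
                        frozen_layers=())
        # joint arm x label stratification keeps placebo-arm classes present
        # in every fine-tune training fold even for small cohorts
        strata = {s.subject_id: f"{s.arm}|{int(s.remission)}" for s in meta}
        folds = make_folds([s.subject_id for s in meta], k=k, seed=seed_m,
                           stratify_by=strata)
        spec_m = replace(spec or ModelSpec(), init_seed=seed_m)
        placebo_ds = ds.subset_subjects(placebo_subjects)
        for it in range(rotations if rotations is not None else k):
            base_model, _ = train_baseline(ds, remission, folds, b_cfg, spec_m, iteration=it)
            fine_model, _ = finetune_placebo(
                base_model, placebo_ds, remission, folds, f_cfg, arms, iteration=it,
            )
            _, _, test_subj = folds.roles(it)
            test_ds = placebo_ds.subset_subjects(test_subj & placebo_subjects)
            if len(test_ds):
                tables.append(predict_table(fine_model, test_ds, model_id=m,
                                            batch_size=f_cfg.batch_size))
            if it == 0:
                models.append((fine_model, folds))
    if not tables:
        warnings.warn("ensemble produced no test predictions", stacklevel=2)
        return pd.DataFrame(), models
    return pd.concat(tables, ignore_index=True), models
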