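"""Fold logic, leakage guards, training loop behaviour, and the freeze contract."""

import numpy as np
import pytest

from placebo_eeg.augment import AugmentConfig
from placebo_eeg.core import N_CHANNELS, SEGMENT_SAMPLES
from placebo_eeg.model import Model, ModelSpec
from placebo_eeg.train import (
    FINETUNE_FROZEN,
    FoldSplit,
    SegmentDataset,
    TrainConfig,
    finetune_placebo,
    make_folds,
    train_baseline,
)

TINY = ModelSpec(
    blocks=((4, 7, 3), (4, 7, 3), (4, 7, 3), (4, 7, 3),
            (6, 7, 2), (6, 7, 2), (6, 7, 2), (6, 7, 2)),
    init_seed=0,
)


def _toy_dataset(rng, n_subjects=10, segs_per_subject=6, effect=6.0):
    """Separable toy data: label-1 subjects carry a 6 Hz tone on two channels."""
    ids, X, labels = [], [], {}
    t = np.arange(SEGMENT_SAMPLES) / 125.0
    for i in range(n_subjects):
        sid = f"s{i:02d}"
        y = i % 2
        labels[sid] = y
        for k in range(segs_per_subject):
            seg = rng.standard_normal((N_CHANNELS, SEGMENT_SAMPLES)) * 8
            if y:
                seg[[6, 11]] += effect * np.sin(2 * np.pi * 6 * t + rng.uniform(0, 6))
            X.append(seg)
            ids.append(sid)
    n = len(X)
    half = segs_per_subject // 2
    return SegmentDataset(
        X=np.asarray(X, dtype=np.float32),
        subject_ids=np.array(ids),
        session_ids=np.array(["A" if k % segs_per_subject < half else "B"
                              for k in range(n)]),
        eye_states=np.array(["EO" if k % 2 else "EC" for k in range(n)]),
        start_s=np.arange(n, dtype=float),
    ), labels


def test_fold_sizes_balanced():
    split = make_folds([f"s{i}" for i in range(10)], k=5, seed=0)
    sizes = np.bincount(list(split.assignment.values()), minlength=5)
    assert list(sizes) == [2, 2, 2, 2, 2]
    split11 = make_folds([f"s{i}" for i in range(11)], k=5, seed=0)
    sizes11 = sorted(np.bincount(list(split11.assignment.values()), minlength=5))
    assert sizes11 == [2, 2, 2, 2, 3]


def test_folds_deterministic_and_error_on_too_few():
    a = make_folds([f"s{i}" for i in range(12)], seed=3).assignment
    b = make_folds([f"s{i}" for i in range(12)], seed=3).assignment
    assert a == b
    with pytest.raises(ValueError, match="at least 5"):
        make_folds(["a", "b"], k=5)
    with pytest.raises(ValueError, match="duplicate"):
        make_folds(["a", "a", "b", "c", "d"])


def test_rotation_partitions_subjects_over_100_splits():
    """Leakage guard: across 100 random splits no subject lands in two roles
    and each fold serves as the test fold exactly once per rotation."""
    subjects = [f"s{i}" for i in range(23)]
    for seed in range(100):
        split = make_folds(subjects, seed=seed)
        test_folds = set()
        for it in range(5):
            train, val, test = split.roles(it)
            assert not (train & val or train & test or val & test)
            assert train | val | test == set(subjects)
            test_folds.add(frozenset(test))
        assert len(test_folds) == 5


def test_eo_ec_sessions_colocate_by_construction():
    """Folds are assigned per subject, so both eye-state sessions of a subject
    inherit one fold; a dataset subset by fold never splits a subject."""
    rng = np.random.default_rng(0)
    ds, labels = _toy_dataset(rng)
    split = make_folds(sorted(set(ds.subject_ids)), seed=1)
    for it in range(5):
        train, _, test = split.roles(it)
        train_ds, test_ds = ds.subset_subjects(train), ds.subset_subjects(test)
        assert not set(train_ds.subject_ids) & set(test_ds.subject_ids)
        for sid in set(test_ds.subject_ids):
            states = set(test_ds.eye_states[test_ds.subject_ids == sid])
            assert states == {"EO", "EC"}


def test_stratified_folds_balance_labels():
    subjects = [f"s{i}" for i in range(20)]
    labels = {s: int(i < 10) for i, s in enumerate(subjects)}
    split = make_folds(subjects, seed=2, stratify_by=labels)
    for fold in range(5):
        members = [s for s, f in split.assignment.items() if f == fold]
        assert sum(labels[s] for s in members) == 2  # 2 of each class per fold


@pytest.fixture(scope="module")
def trained_pair():
    rng = np.random.default_rng(7)
    ds, labels = _toy_dataset(rng)
    folds = make_folds(sorted(labels), seed=0, stratify_by=labels)
    bcfg = TrainConfig(stage="baseline", lr=5e-3, batch_size=16, max_epochs=4,
                       seed=1, augment=None)
    model, history = train_baseline(ds, labels, folds, bcfg, TINY)
    return ds, labels, folds, model, history


def test_baseline_training_learns_separable_toy_task(trained_pair):
    ds, labels, folds, model, history = trained_pair
    assert len(history) <= 4 and all("val_loss" in h for h in history)
    from sklearn.metrics import roc_auc_score

    _, val, _ = folds.roles(0)
    val_ds = ds.subset_subjects(val)
    logits = model.predict_logits_batched(val_ds.X)
    y = np.array([labels[s] for s in val_ds.subject_ids])
    assert roc_auc_score(y, logits) > 0.5


def test_single_class_training_labels_rejected(trained_pair):
    ds, labels, folds, *_ = trained_pair
    bad = {s: 1 for s in labels}
    with pytest.raises(ValueError, match="single-class"):
        train_baseline(ds, bad, folds, TrainConfig(stage="baseline", max_epochs=1,
                                                   augment=None), TINY)


def test_finetune_freezes_everything_below_l8(trained_pair):
    ds, labels, folds, baseline, _ = trained_pair
    arms = {s: "placebo" for s in labels}
    fcfg = TrainConfig(stage="finetune", lr=1e-2, batch_size=16, max_epochs=2,
                       seed=2, augment=None)
    assert fcfg.frozen_layers == FINETUNE_FROZEN
    model, _ = finetune_placebo(baseline, ds, labels, folds, fcfg, arms)
    base_state = baseline.state_dict()
    for k, v in model.state_dict().items():
        block = k.removeprefix("buffer::").split(".")[0]
        if block in FINETUNE_FROZEN:
            np.testing.assert_array_equal(v, base_state[k], err_msg=k)


def test_finetune_rejects_non_placebo_subjects(trained_pair):
    ds, labels, folds, baseline, _ = trained_pair
    arms = {s: "drug" for s in labels}
    with pytest.raises(ValueError, match="non-placebo"):
        finetune_placebo(baseline, ds, labels, folds,
                         TrainConfig(stage="finetune", max_epochs=1, augment=None), arms)


def test_training_is_deterministic_given_seed():
    rng = np.random.default_rng(9)
    ds, labels = _toy_dataset(rng, n_subjects=6, segs_per_subject=4)
    folds = make_folds(sorted(labels), seed=0)
    cfg = TrainConfig(stage="baseline", lr=5e-3, batch_size=8, max_epochs=2, seed=5,
                      augment=AugmentConfig())
    m1, h1 = train_baseline(ds, labels, folds, cfg, TINY)
    m2, h2 = train_baseline(ds, labels, folds, cfg, TINY)
    assert h1 == h2
    for k, v in m1.state_dict().items():
        np.testing.assert_array_equal(v, m2.state_dict()[k])


def test_early_stopping_bounds_history_length():
    rng = np.random.default_rng(11)
    ds, labels = _toy_dataset(rng, n_subjects=6, segs_per_subject=4, effect=0.0)
    folds = make_folds(sorted(labels), seed=0)
    cfg = TrainConfig(stage="baseline", lr=1e-4, batch_size=8, max_epochs=60,
                      early_stop_epochs=5, seed=0, augment=None)
    _, history = train_baseline(ds, labels, folds, cfg, TINY)
    best = int(np.argmin([h["val_loss"] for h in history]))
    assert len(history) <= best + 5 + 1


def test_plateau_scheduler_halves_learning_rate():
    rng = np.random.default_rng(13)
    ds, labels = _toy_dataset(rng, n_subjects=6, segs_per_subject=4, effect=0.0)
    folds = make_folds(sorted(labels), seed=0)
    cfg = TrainConfig(stage="baseline", lr=1e-4, batch_size=8, max_epochs=30,
                      plateau_patience=3, early_stop_epochs=30, seed=0, augment=None)
    _, history = train_baseline(ds, labels, folds, cfg, TINY)
    lrs = {h["lr"] for h in history}
    assert any(lr <= 1e-4 / 2 + 1e-12 for lr in lrs)


def test_config_stage_validation():
    with pytest.raises(ValueError, match="frozen_layers"):
        TrainConfig(stage="baseline", frozen_layers=("L1",))
    cfg = TrainConfig(stage="finetune")
    assert cfg.lr == 1e-4 and cfg.frozen_layers == FINETUNE_FROZEN
    assert TrainConfig(stage="baseline").lr == 3e-5
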