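"""Packaged synthetic validation studies.

Two self-contained studies exercise the pipeline end to end on cohorts with
known ground truth:

* :func:`recovery_study` — generates a 60-subject cohort with strong
  planted theta/lower-beta effects, runs preprocessing and the two-stage
  training over three cross-validation rotations, and scores held-out
  placebo subjects; optionally with permuted labels as a negative control.
* :func:`regression_recovery` / :func:`null_calibration` — parameter
  recovery and type-I behaviour of the participant-bootstrapped band-power
  regression at n = 200.

Both are deterministic given their seed and sized to run in minutes on one
CPU core; the acceptance script and the test suite call them directly.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .core import SegmentSet
from .model import ModelSpec, SMOKE_BLOCKS
from .preprocess import preprocess_recording
from .synth import CohortSpec, generate_cohort
from .train import TrainConfig, dataset_from_segments, train_ensemble
from . import evaluate as ev

__all__ = ["recovery_study", "oracle_reference_auc", "regression_recovery",
           "null_calibration"]

#: Study conditions of the synthetic recovery cohort.
RECOVERY_COHORT = dict(n_subjects=60, duration_s=24.0, effect_theta=-2.0,
                       effect_beta_low=-2.0, artifact_rates={})
#: Optimization point for the smoke-scale model (see docs/methods.md): the
#: baseline trains from random init with a validation-selected restart; the
#: fine-tune stage uses a milder rate so stage two refines rather than
#: overwrites the baseline features, with the incoming checkpoint competing
#: during selection.
RECOVERY_TRAIN = dict(weight_decay=0.01, batch_size=32, max_epochs=26,
                      early_stop_epochs=12)
RECOVERY_BASELINE_LR = 1e-2
RECOVERY_FINETUNE_LR = 3e-3
RECOVERY_ROTATIONS = 3


def _prepare(seed: int):
    spec = CohortSpec(seed=seed, **RECOVERY_COHORT)
    recordings, subjects = generate_cohort(spec)
    segset = SegmentSet.concatenate([preprocess_recording(r) for r in recordings])
    return dataset_from_segments(segset), subjects


def _permute_labels(subjects, seed: int):
    rng = np.random.default_rng(seed)
    permuted = rng.permutation([s.remission for s in subjects])
    out = []
    for s, y in zip(subjects, permuted):
        s2 = copy.copy(s)
        s2.endpoint_score = 5 if y else 12
        s2.remission = bool(y)
        out.append(s2)
    return out


def recovery_study(seed: int, permute_labels: bool = False,
                   _cache: dict | None = None) -> dict:
    """Run the two-stage recovery pipeline; returns subject-level metrics.

    ``_cache`` (a dict) lets callers reuse the generated/preprocessed
    cohort between the real and permuted arms.
    """
    cohort_seed = seed % (2**31 - 1)
    if _cache is not None and _cache.get("seed") == cohort_seed:
        ds, subjects = _cache["data"]
    else:
        ds, subjects = _prepare(cohort_seed)
        if _cache is not None:
            _cache.update(seed=cohort_seed, data=(ds, subjects))
    if permute_labels:
        subjects = _permute_labels(subjects, (seed + 104729) % (2**31 - 1))
    base_seed = (seed + 11) % (2**31 - 1)
    preds, _ = train_ensemble(
        ds, subjects, n_models=1, base_seed=base_seed,
        baseline_cfg=TrainConfig(stage="baseline", lr=RECOVERY_BASELINE_LR,
                                 restarts=1, augment=AugmentConfig(), **RECOVERY_TRAIN),
        finetune_cfg=TrainConfig(stage="finetune", lr=RECOVERY_FINETUNE_LR,
                                 restarts=0, augment=AugmentConfig(), **RECOVERY_TRAIN),
        spec=ModelSpec(blocks=SMOKE_BLOCKS),
        rotations=RECOVERY_ROTATIONS,
    )
    remission = {s.subject_id: int(s.remission) for s in subjects}
    labels = {k: remission[k] for k in set(preds["subject_id"])}
    metrics = ev.compute_metrics(ev.aggregate_subject_scores(preds), labels)
    metrics["n_subjects"] = len(labels)
    return metrics


def oracle_reference_auc(seed: int, _cache: dict | None = None) -> dict:
    """Ceiling reference for the recovery study: a logistic model on the six
    planted log band powers (subject-level means), trained on each rotation's
    train+validation subjects and scored on the same held-out placebo
    subjects the CNN is scored on.  Because this oracle reads exactly the
    features the generator plants, its AUC approximates the information
    ceiling of the cohort at the committed effect size.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    from .core import CANONICAL_CHANNELS, SEGMENT_RATE_HZ
    from .spectra import _welch_band_powers
    from .train import make_folds

    cohort_seed = seed % (2**31 - 1)
    if _cache is not None and _cache.get("seed") == cohort_seed:
        ds, subjects = _cache["data"]
    else:
        ds, subjects = _prepare(cohort_seed)
        if _cache is not None:
            _cache.update(seed=cohort_seed, data=(ds, subjects))
    planted = [("Fz", "theta"), ("Cz", "theta"), ("F8", "theta"), ("C3", "theta"),
               ("F3", "beta_low"), ("F4", "beta_low")]
    bands = {"theta": (4.0, 8.0), "beta_low": (13.0, 20.0)}
    feats: dict[str, list] = {}
    for seg, sid in zip(ds.X, ds.subject_ids):
        powers = _welch_band_powers(np.asarray(seg, dtype=float), SEGMENT_RATE_HZ, bands)
        row = [np.log(powers[band][CANONICAL_CHANNELS.index(ch)] + 1e-12)
               for ch, band in planted]
        feats.setdefault(sid, []).append(row)
    X = {k: np.mean(v, axis=0) for k, v in feats.items()}
    remission = {s.subject_id: int(s.remission) for s in subjects}
    arms = {s.subject_id: s.arm for s in subjects}
    strata = {s.subject_id: f"{s.arm}|{int(s.remission)}" for s in subjects}
    base_seed = (seed + 11) % (2**31 - 1)
    folds = make_folds([s.subject_id for s in subjects], seed=base_seed,
                       stratify_by=strata)
    scores, labels = [], []
    for it in range(RECOVERY_ROTATIONS):
        train, val, test = folds.roles(it)
        fit_ids = sorted(train | val)
        clf = LogisticRegression(max_iter=2000).fit(
            [X[s] for s in fit_ids], [remission[s] for s in fit_ids])
        test_pl = sorted(s for s in test if arms[s] == "placebo")
        scores += list(clf.decision_function([X[s] for s in test_pl]))
        labels += [remission[s] for s in test_pl]
    return {"auc": float(roc_auc_score(labels, scores)), "n_subjects": len(labels)}


# --- band-power regression studies ------------------------------------------

def _regression_dataset(seed: int, coef: float, n_predictors: int,
                        n_subjects: int = 200):
    """Session-level scores linear in the z-scored power of predictor 0."""
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:03d}" for i in range(n_subjects)]
    meta = pd.DataFrame({"subject_id": subjects,
                         "sex": rng.choice(["male", "female"], n_subjects)})
    vals: dict = {}
    for s in subjects:
        # independent lognormal power per (subject, predictor); sessions of a
        # subject share the base so the participant bootstrap has structure
        bases = rng.normal(3.0, 0.5, size=n_predictors)
        for ses in ("ses-EO", "ses-EC"):
            for j in range(n_predictors):
                vals[(s, ses, j)] = np.exp(bases[j] + 0.1 * rng.standard_normal())
    v0 = np.array([vals[(s, ses, 0)] for s in subjects for ses in ("ses-EO", "ses-EC")])
    z0 = (v0 - v0.mean()) / v0.std()
    rows_p, rows_s, k = [], [], 0
    for s in subjects:
        for ses, eye in (("ses-EO", "EO"), ("ses-EC", "EC")):
            rows_s.append((s, ses, 0.5 + coef * z0[k] + 0.03 * rng.standard_normal()))
            for j in range(n_predictors):
                rows_p.append((s, ses, eye, f"ch{j}", "theta", vals[(s, ses, j)]))
            k += 1
    powers = pd.DataFrame(rows_p, columns=["subject_id", "session_id", "eye_state",
                                           "channel", "band", "power"])
    scores = pd.DataFrame(rows_s, columns=["subject_id", "session_id", "score"])
    return scores, powers, meta


def regression_recovery(seed: int, coef: float = -0.1, n_boot: int = 200):
    """Recover a planted standardized coefficient at n = 200 participants."""
    from .spectra import bootstrap_regression

    scores, powers, meta = _regression_dataset(seed % (2**31 - 1), coef, 1)
    return bootstrap_regression(scores, powers, [("ch0", "theta")], meta,
                                n_boot=n_boot, seed=(seed + 1) % (2**31 - 1))[0]


def null_calibration(seed: int, n_predictors: int = 40, n_boot: int = 200) -> dict:
    """Zero-effect predictors: fraction whose bootstrap CI excludes zero."""
    from .spectra import bootstrap_regression

    scores, powers, meta = _regression_dataset((seed + 2) % (2**31 - 1), 0.0, n_predictors)
    results = bootstrap_regression(
        scores, powers, [(f"ch{j}", "theta") for j in range(1, n_predictors)],
        meta, n_boot=n_boot, seed=(seed + 3) % (2**31 - 1))
    rate = float(np.mean([r.significant for r in results]))
    return {"rate": rate, "n_predictors": len(results)}
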