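"""Ensemble bootstrap aggregation and the binary-classification metric suite.

Per-segment predictions from the model ensemble are averaged hierarchically
— across models for each segment, across segments for each session, across
sessions for each subject — yielding one placebo-response score per subject.
Uncertainty comes from a bootstrap that resamples the model axis per segment
(1,000 repetitions by default); every metric is reported as mean ± SD over
the bootstrap distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn

__all__ = [
    "MetricsReport", "aggregate_subject_scores", "compute_metrics", "bootstrap_metrics",
]

_EPS = 1e-12


@dataclass
class MetricsReport:
    """Mean ± SD of each metric over the bootstrap distribution."""

    loss: tuple[float, float]
    auc: tuple[float, float]
    bacc: tuple[float, float]
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    n_boot: int

    def to_dict(self) -> dict:
        return {
            name: {"mean": mu, "sd": sd}
            for name, (mu, sd) in [
                ("loss", self.loss), ("auc", self.auc), ("bacc", self.bacc),
                ("sensitivity", self.sensitivity), ("specificity", self.specificity),
            ]
        } | {"n_boot": self.n_boot}


def _check_preds(preds: pd.DataFrame) -> pd.DataFrame:
    if preds.empty:
        raise ValueError("prediction table is empty")
    required = {"model_id", "subject_id", "session_id", "segment_idx", "probability"}
    missing = required - set(preds.columns)
    if missing:
        raise ValueError(f"prediction table lacks columns: {sorted(missing)}")
    return preds


def aggregate_subject_scores(preds: pd.DataFrame) -> pd.Series:
    """Hierarchical mean: models -> segments -> sessions -> one subject score.

    Subjects with zero segments simply do not appear (callers warn upstream
    when a subject loses every segment to artifact rejection).
    """
    preds = _check_preds(preds)
    seg = preds.groupby(["subject_id", "session_id", "segment_idx"], sort=True)["probability"].mean()
    ses = seg.groupby(["subject_id", "session_id"]).mean()
    return ses.groupby("subject_id").mean().rename("score")


def compute_metrics(
    scores: pd.Series | dict,
    labels: dict,
    threshold: float = 0.5,
) -> dict:
    """Point metrics at an operating threshold on aggregated probabilities.

    AUC uses the rank statistic (tie-aware); loss is binary cross-entropy
    computed from the score's logit; precision/recall/F1 ride along.
    """
    scores = pd.Series(scores)
    y = np.array([labels[s] for s in scores.index], dtype=float)
    p = np.clip(scores.to_numpy(dtype=float), _EPS, 1 - _EPS)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; AUC is undefined")
    logits = np.log(p / (1 - p))
    loss, _ = nn.bce_with_logits(logits, y)
    pred = (p >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (y == 1)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    sens = tp / max(tp + fn, _EPS)
    spec = tn / max(tn + fp, _EPS)
    precision = tp / max(tp + fp, _EPS)
    f1 = 2 * precision * sens / max(precision + sens, _EPS)
    return {
        "loss": loss,
        "auc": float(roc_auc_score(y, p)),
        "bacc": 0.5 * (sens + spec),
        "sensitivity": sens,
        "specificity": spec,
        "precision": precision,
        "recall": sens,
        "f1": f1,
    }


def bootstrap_metrics(
    preds: pd.DataFrame,
    labels: dict,
    n_boot: int = 1000,
    threshold: float = 0.5,
    seed: int = 0,
    unit: str = "model",
) -> MetricsReport:
    """Bootstrap the ensemble: per repetition, draw model predictions with
    replacement for every segment (same count as models), aggregate
    hierarchically, and score subjects against ``labels``.

    ``unit="subject"`` switches to a conventional subject-level bootstrap
    for robustness checks.
    """
    preds = _check_preds(preds)
    if unit not in ("model", "subject"):
        raise ValueError(f"unknown bootstrap unit {unit!r}")
    rng = np.random.default_rng(seed)

    # wide matrix: rows = (subject, session, segment), cols = models
    wide = preds.pivot_table(
        index=["subject_id", "session_id", "segment_idx"],
        columns="model_id", values="probability", aggfunc="mean",
    )
    probs = wide.to_numpy()  # [n_segments, n_models], NaN where a model lacks a row
    seg_index = wide.index.to_frame(index=False)
    subjects = sorted(seg_index["subject_id"].unique())
    y_all = np.array([labels[s] for s in subjects], dtype=float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("labels are single-class; AUC is undefined")

    rows = []
    for _ in range(n_boot):
        if unit == "model":
            n_models = probs.shape[1]
            draw = np.empty(len(probs))
            cols = rng.integers(0, n_models, size=(len(probs), n_models))
            sampled = np.take_along_axis(probs, cols, axis=1)
            with np.errstate(invalid="ignore"):
                draw = np.nanmean(sampled, axis=1)
            boot = seg_index.assign(probability=draw).dropna(subset=["probability"])
            boot_labels = labels
        else:
            picked = rng.choice(subjects, size=len(subjects), replace=True)
            parts, boot_labels = [], {}
            for j, s in enumerate(picked):
                rows_s = seg_index["subject_id"] == s
                part = seg_index[rows_s].copy()
                part["probability"] = np.nanmean(probs[rows_s.to_numpy()], axis=1)
                part["subject_id"] = f"{s}#{j}"
                boot_labels[f"{s}#{j}"] = labels[s]
                parts.append(part)
            boot = pd.concat(parts, ignore_index=True)
        if len(np.unique([boot_labels[s] for s in boot["subject_id"].unique()])) < 2:
            continue  # degenerate resample
        boot = boot.assign(model_id=0)
        scores = aggregate_subject_scores(boot)
        rows.append(compute_metrics(scores, boot_labels, threshold))

    if not rows:
        raise ValueError("no valid bootstrap repetition (labels degenerate?)")
    frame = pd.DataFrame(rows)

    def ms(col: str) -> tuple[float, float]:
        return float(frame[col].mean()), float(frame[col].std(ddof=0))

    return MetricsReport(
        loss=ms("loss"), auc=ms("auc"), bacc=ms("bacc"),
        sensitivity=ms("sensitivity"), specificity=ms("specificity"),
        n_boot=len(frame),
    )
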