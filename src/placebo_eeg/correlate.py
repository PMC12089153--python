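"""Holm-corrected Pearson screening of prediction scores against metadata.

Given one placebo-response score per subject and a family of behavioural /
demographic covariates, each covariate is tested by two-sided Pearson
correlation on pairwise-complete observations and the family is adjusted by
Holm's step-down procedure (family-wise error control without the
independence assumptions of stricter single-step corrections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationResult", "correlate_covariates", "holm_adjust"]


@dataclass
class CorrelationResult:
    variable: str
    r: float
    n: int
    p_raw: float
    p_adj: float
    significant: bool
    skipped: bool = False

    def to_row(self) -> dict:
        return {
            "variable": self.variable, "r": self.r, "n": self.n,
            "p_raw": self.p_raw, "p_adj": self.p_adj,
            "significant": self.significant, "skipped": self.skipped,
        }


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving in the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
    return p_adj


def correlate_covariates(
    scores: dict | pd.Series,
    meta: pd.DataFrame,
    family: list[str],
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """One Pearson test per covariate in ``family``, Holm-adjusted jointly.

    ``meta`` must carry ``subject_id`` plus the covariate columns; missing
    values are dropped pairwise.  Zero-variance covariates (or families with
    fewer than 3 complete pairs) are reported as skipped and excluded from
    the Holm family.
    """
    scores = pd.Series(scores)
    merged = meta.set_index("subject_id").join(scores.rename("score"), how="inner")
    results: list[CorrelationResult] = []
    tested: list[CorrelationResult] = []
    for var in family:
        if var not in merged.columns:
            raise KeyError(f"covariate {var!r} not in metadata")
        sub = merged[["score", var]].dropna()
        x = sub[var].to_numpy(dtype=float)
        y = sub["score"].to_numpy(dtype=float)
        if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
            results.append(CorrelationResult(var, float("nan"), len(sub),
                                             float("nan"), float("nan"),
                                             significant=False, skipped=True))
            continue
        r, p = spstats.pearsonr(x, y)
        res = CorrelationResult(var, float(r), len(sub), float(p), float("nan"),
                                significant=False)
        results.append(res)
        tested.append(res)
    if tested:
        adj = holm_adjust([t.p_raw for t in tested])
        for res, pa in zip(tested, adj):
            res.p_adj = float(pa)
            res.significant = bool(pa < alpha)
    return results


def results_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular form with significance stars (`*` <0.05, `**` <0.005, `***` <0.001)."""
    frame = pd.DataFrame([r.to_row() for r in results])
    def stars(p: float) -> str:
        if not np.isfinite(p):
            return "skipped"
        return "***" if p < 0.001 else "**" if p < 0.005 else "*" if p < 0.05 else "ns"
    frame["stars"] = frame["p_adj"].map(stars)
    return frame
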