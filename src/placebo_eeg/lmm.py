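"""Random-intercept linear mixed model via profiled REML.

The band-power regressions refit the same small mixed model thousands of
times inside a participant bootstrap, so this solver is specialized for the
one-random-intercept case: the covariance has a single variance ratio
``lambda = sigma_u^2 / sigma_e^2``, the REML criterion is profiled down to a
scalar function of ``lambda``, and each evaluation costs O(n p^2) using
group-wise sufficient statistics.  Agreement with a general mixed-model
implementation is covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


class SingularFitError(ValueError):
    """Design matrix is rank-deficient under the working covariance."""


@dataclass
class LMMResult:
    """Fixed effects and variance components of a random-intercept fit."""

    names: list[str]
    coef: np.ndarray
    bse: np.ndarray
    sigma_u2: float
    sigma_e2: float
    lam: float  # sigma_u2 / sigma_e2
    reml: float

    def coef_named(self) -> dict:
        return dict(zip(self.names, self.coef))


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Sort by group; return per-group slices and sufficient statistics."""
    order = np.argsort(groups, kind="stable")
    Xs, ys, gs = X[order], y[order], groups[order]
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    sizes = np.diff(np.r_[starts, len(gs)])
    sum_x = np.add.reduceat(Xs, starts, axis=0)  # [G, p]
    sum_y = np.add.reduceat(ys, starts)  # [G]
    return Xs, ys, sizes, sum_x, sum_y


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
) -> LMMResult:
    """REML fit of ``y = X b + u[group] + e`` with a scalar profile search.

    ``X`` must include the intercept column if one is wanted.  Raises
    :class:`SingularFitError` when the weighted normal equations are
    numerically singular.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if n <= p:
        raise SingularFitError(f"{n} rows cannot identify {p} fixed effects")
    Xs, ys, sizes, sum_x, sum_y = _group_stats(X, y, groups)
    xtx = Xs.T @ Xs
    xty = Xs.T @ ys
    yty = float(ys @ ys)

    def weighted_normal_eqs(lam: float):
        w = lam / (1.0 + sizes * lam)  # [G]
        xtwx = xtx - (sum_x * w[:, None]).T @ sum_x
        xtwy = xty - sum_x.T @ (w * sum_y)
        ytwy = yty - float(sum_y @ (w * sum_y))
        return xtwx, xtwy, ytwy

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        xtwx, xtwy, ytwy = weighted_normal_eqs(lam)
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytwy - float(beta @ xtwy)
        if rss <= 0:
            return np.inf
        logdet_v = float(np.sum(np.log1p(sizes * lam)))
        return (n - p) * np.log(rss) + logdet_v + logdet_xtwx

    res = minimize_scalar(neg2_reml, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    # compare against the lambda -> 0 boundary (pure fixed-effects model)
    candidates = [(neg2_reml(-30.0), 0.0), (res.fun, float(np.exp(res.x)))]
    crit, lam = min(candidates, key=lambda t: t[0])
    if not np.isfinite(crit):
        raise SingularFitError("REML criterion is not finite; singular design")

    xtwx, xtwy, ytwy = weighted_normal_eqs(lam)
    try:
        cond = np.linalg.cond(xtwx)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        raise SingularFitError("weighted normal equations are singular")
    if not np.isfinite(cond) or cond > 1e10:
        raise SingularFitError("design matrix is numerically rank-deficient")
    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - float(beta @ xtwy)
    sigma_e2 = rss / (n - p)
    sigma_u2 = lam * sigma_e2
    cov = sigma_e2 * np.linalg.inv(xtwx)
    return LMMResult(
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
        coef=beta,
        bse=np.sqrt(np.clip(np.diag(cov), 0.0, None)),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        lam=float(lam),
        reml=float(-0.5 * crit),
    )
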