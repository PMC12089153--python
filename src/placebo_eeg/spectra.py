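"""Band power extraction and the bootstrapped band-power regression.

Absolute spectral power is computed per channel by Welch's method (4-s Hann
windows, 50% overlap) and integrated over four bands: theta 4-8 Hz, alpha
8-13 Hz, lower beta 13-20 Hz, upper beta 20-30 Hz.  Each (channel, band)
predictor then enters its own mixed-effects model

    score ~ z(power) + sex * eye_state,   random intercept per subject

fitted to session-level prediction scores.  Inference is by participant
bootstrap: subjects are resampled with replacement (their sessions travel
together), the predictor is re-standardized within every resample, and an
effect is significant when the two-tailed 5% percentile interval of its
coefficient distribution excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Recording, SegmentSet, SEGMENT_RATE_HZ
from .lmm import SingularFitError, fit_random_intercept

__all__ = [
    "POWER_BANDS", "RegressionResult", "band_power", "band_power_segments",
    "fit_mixed_model", "bootstrap_regression",
]

#: Analysis bands, Hz.
POWER_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta_low": (13.0, 20.0),
    "beta_high": (20.0, 30.0),
}

_FIXED_EFFECTS = ["intercept", "power", "sex", "eye_state", "sex:eye_state"]


@dataclass
class RegressionResult:
    """Bootstrap summary for one (channel, band) predictor."""

    channel: str
    band: str
    coef_mean: float
    coef_sd: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int
    n_singular: int
    fixed_effects: dict  # mean bootstrap coefficient per fixed effect

    def to_row(self) -> dict:
        return {
            "channel": self.channel, "band": self.band,
            "coef_mean": self.coef_mean, "coef_sd": self.coef_sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "significant": self.significant, "n_boot": self.n_boot,
        }


def _welch_band_powers(data: np.ndarray, fs: float, bands: dict) -> dict:
    """Integrated PSD per band for a [n_channels x n_samples] array (µV²)."""
    for name, (lo, hi) in bands.items():
        if hi > fs / 2:
            raise ValueError(f"band {name!r} ({lo}-{hi} Hz) exceeds the Nyquist rate {fs / 2} Hz")
    nper = min(int(4 * fs), data.shape[1])
    freqs, psd = sps.welch(data, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, axis=1)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = np.trapezoid(psd[:, sel], freqs[sel], axis=1)
    return out


def band_power(source: Recording | SegmentSet, bands: dict | None = None) -> pd.DataFrame:
    """BandPowerTable: one row per (subject, session, channel, band), µV².

    For a :class:`SegmentSet` the session-level power is the mean over that
    session's kept segments.
    """
    bands = bands or POWER_BANDS
    if isinstance(source, Recording):
        if source.rate_hz < 60:
            raise ValueError("sampling rate below 60 Hz cannot resolve upper beta")
        powers = _welch_band_powers(source.data, source.rate_hz, bands)
        rows = []
        for ci, ch in enumerate(source.channels):
            for band in bands:
                rows.append({
                    "subject_id": source.subject_id, "session_id": source.session_id,
                    "eye_state": source.eye_state, "channel": ch, "band": band,
                    "power": float(powers[band][ci]),
                })
        return pd.DataFrame(rows)
    return band_power_segments(source, bands)


def band_power_segments(segset: SegmentSet, bands: dict | None = None) -> pd.DataFrame:
    bands = bands or POWER_BANDS
    from .core import CANONICAL_CHANNELS

    idx = segset.kept_index()
    data = segset.kept_data()
    if not len(data):
        return pd.DataFrame(columns=["subject_id", "session_id", "eye_state", "channel", "band", "power"])
    per_seg = []
    for seg, info in zip(data, idx):
        powers = _welch_band_powers(seg, SEGMENT_RATE_HZ, bands)
        for ci, ch in enumerate(CANONICAL_CHANNELS):
            for band in bands:
                per_seg.append({
                    "subject_id": info["subject_id"], "session_id": info["session_id"],
                    "eye_state": info["eye_state"], "channel": ch, "band": band,
                    "power": float(powers[band][ci]),
                })
    frame = pd.DataFrame(per_seg)
    return (
        frame.groupby(["subject_id", "session_id", "eye_state", "channel", "band"],
                      as_index=False)["power"].mean()
    )


def _design_frame(
    scores: pd.DataFrame,
    powers: pd.DataFrame,
    predictor: tuple[str, str],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (subject, session): score, predictor power, sex, eye."""
    channel, band = predictor
    pw = powers[(powers["channel"] == channel) & (powers["band"] == band)]
    if pw.empty:
        raise ValueError(f"no band-power rows for predictor ({channel}, {band})")
    frame = scores.merge(
        pw[["subject_id", "session_id", "eye_state", "power"]],
        on=["subject_id", "session_id"], how="inner",
    )
    sex_map = meta.set_index("subject_id")["sex"].astype(str)
    frame["sex"] = frame["subject_id"].map(sex_map).map({"male": 1.0, "female": 0.0})
    frame["eye"] = (frame["eye_state"] == "EC").astype(float)
    if frame[["score", "power", "sex"]].isna().any().any():
        raise ValueError("design frame has missing values (unmatched metadata?)")
    return frame


def _fit_frame(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fit the mixed model on a design frame; returns (coef, names)."""
    zp_sd = frame["power"].std(ddof=0)
    if zp_sd <= 0:
        raise SingularFitError("predictor power has zero variance")
    zp = (frame["power"] - frame["power"].mean()) / zp_sd
    X = np.column_stack([
        np.ones(len(frame)), zp, frame["sex"], frame["eye"], frame["sex"] * frame["eye"],
    ])
    res = fit_random_intercept(frame["score"].to_numpy(), X,
                               frame["group"].to_numpy(), names=_FIXED_EFFECTS)
    return res.coef, res.names


def fit_mixed_model(
    scores: pd.DataFrame,
    powers: pd.DataFrame,
    predictor: tuple[str, str],
    meta: pd.DataFrame,
) -> dict:
    """Single mixed-effects fit; returns named fixed-effect coefficients.

    ``scores``: columns subject_id, session_id, score (session-level
    aggregated prediction).  The predictor is z-scored across rows before
    fitting so coefficients are comparable across channels and bands.
    """
    frame = _design_frame(scores, powers, predictor, meta)
    frame = frame.assign(group=frame["subject_id"])
    try:
        coef, names = _fit_frame(frame)
    except SingularFitError:
        if frame["power"].std(ddof=0) <= 0:
            return {name: 0.0 for name in _FIXED_EFFECTS} | {"singular": True}
        raise
    return dict(zip(names, coef)) | {"singular": False}


def bootstrap_regression(
    scores: pd.DataFrame,
    powers: pd.DataFrame,
    predictors: list[tuple[str, str]],
    meta: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[RegressionResult]:
    """Participant bootstrap of the band-power regression for each predictor."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a stable percentile CI")
    results = []
    for p_idx, predictor in enumerate(predictors):
        frame = _design_frame(scores, powers, predictor, meta)
        subjects = frame["subject_id"].unique()
        # numpy views grouped by subject: the bootstrap assembles row indices
        # and refits without touching pandas
        y_all = frame["score"].to_numpy(dtype=float)
        power_all = frame["power"].to_numpy(dtype=float)
        sex_all = frame["sex"].to_numpy(dtype=float)
        eye_all = frame["eye"].to_numpy(dtype=float)
        subj_codes = pd.Categorical(frame["subject_id"], categories=subjects).codes
        rows_of = [np.flatnonzero(subj_codes == j) for j in range(len(subjects))]
        rng = np.random.default_rng([seed, p_idx])
        coefs, fixed_rows, n_singular = [], [], 0
        for _ in range(n_boot):
            picked = rng.integers(0, len(subjects), size=len(subjects))
            rows = np.concatenate([rows_of[j] for j in picked])
            groups = np.repeat(np.arange(len(picked)), [len(rows_of[j]) for j in picked])
            pw = power_all[rows]
            sd = pw.std()
            if sd <= 0:
                n_singular += 1
                continue
            zp = (pw - pw.mean()) / sd
            sex = sex_all[rows]
            eye = eye_all[rows]
            X = np.column_stack([np.ones(len(rows)), zp, sex, eye, sex * eye])
            try:
                res = fit_random_intercept(y_all[rows], X, groups, names=_FIXED_EFFECTS)
            except SingularFitError:
                n_singular += 1
                continue
            coefs.append(res.coef[1])
            fixed_rows.append(res.coef)
        if n_singular:
            warnings.warn(
                f"{n_singular}/{n_boot} singular bootstrap fits for {predictor}", stacklevel=2
            )
        if len(coefs) < max(10, n_boot // 2):
            raise SingularFitError(f"too few successful bootstrap fits for {predictor}")
        coefs = np.array(coefs)
        lo, hi = np.percentile(coefs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        fixed_mean = np.mean(fixed_rows, axis=0)
        results.append(RegressionResult(
            channel=predictor[0], band=predictor[1],
            coef_mean=float(coefs.mean()), coef_sd=float(coefs.std(ddof=0)),
            ci_low=float(lo), ci_high=float(hi),
            significant=bool(lo > 0 or hi < 0),
            n_boot=len(coefs), n_singular=n_singular,
            fixed_effects=dict(zip(_FIXED_EFFECTS, map(float, fixed_mean))),
        ))
    return results
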