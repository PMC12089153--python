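"""Band power extraction and the bootstrapped random-intercept regression."""

import numpy as np
import pandas as pd
import pytest

from placebo_eeg.core import CANONICAL_CHANNELS, Recording
from placebo_eeg.lmm import SingularFitError, fit_random_intercept
from placebo_eeg.spectra import (
    POWER_BANDS,
    band_power,
    bootstrap_regression,
    fit_mixed_model,
)


def _tone_recording(freq, fs=250.0, dur=30.0, amp=10.0):
    t = np.arange(int(dur * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (19, 1))
    return Recording("s0", "ses-A", "EO", fs, CANONICAL_CHANNELS, data)


@pytest.mark.parametrize("freq,band", [(10.0, "alpha"), (6.0, "theta")])
def test_pure_tone_concentrates_in_its_band(freq, band):
    table = band_power(_tone_recording(freq))
    ch = table[table.channel == "Cz"].set_index("band")["power"]
    assert ch[band] / ch.sum() >= 0.90


def test_zero_signal_gives_zero_power():
    rec = Recording("s0", "A", "EO", 250.0, CANONICAL_CHANNELS, np.zeros((19, 5000)))
    assert np.allclose(band_power(rec)["power"], 0.0)


def test_band_above_nyquist_raises():
    with pytest.raises(ValueError, match="sampling rate"):
        band_power(_tone_recording(10.0, fs=50.0))
    with pytest.raises(ValueError, match="gamma"):
        band_power(_tone_recording(10.0, fs=100.0), bands={"gamma": (40.0, 80.0)})


def test_band_powers_bounded_by_total_power(clean_recording):
    table = band_power(clean_recording)
    from scipy.signal import welch

    f, psd = welch(clean_recording.data, fs=clean_recording.rate_hz,
                   nperseg=int(4 * clean_recording.rate_hz))
    sel = (f >= 0.5) & (f <= 62.5)
    total = np.trapezoid(psd[:, sel], f[sel], axis=1)
    for ci, ch in enumerate(clean_recording.channels):
        band_sum = table[table.channel == ch]["power"].sum()
        assert band_sum <= total[ci] * 1.02


# --- random-intercept solver ------------------------------------------------

def _sim_lmm(rng, n_subjects=60, sigma_u=0.3, beta=(-0.1, 0.5)):
    rows = []
    for i in range(n_subjects):
        u = sigma_u * rng.standard_normal()
        for _ in range(2):
            x = rng.standard_normal()
            y = beta[1] + beta[0] * x + u + 0.2 * rng.standard_normal()
            rows.append((f"s{i}", x, y))
    df = pd.DataFrame(rows, columns=["g", "x", "y"])
    X = np.column_stack([np.ones(len(df)), df.x])
    return df, X


def test_random_intercept_matches_statsmodels_mixedlm(rng):
    import statsmodels.formula.api as smf

    df, X = _sim_lmm(rng)
    res = fit_random_intercept(df.y.to_numpy(), X, df.g.to_numpy(), names=["int", "x"])
    sm_res = smf.mixedlm("y ~ x", df, groups=df.g).fit(reml=True)
    assert res.coef[1] == pytest.approx(sm_res.params["x"], abs=1e-4)
    assert res.coef[0] == pytest.approx(sm_res.params["Intercept"], abs=1e-4)
    assert res.sigma_e2 == pytest.approx(sm_res.scale, rel=0.05)


def test_singular_design_raises():
    y = np.arange(10.0)
    X = np.column_stack([np.ones(10), np.ones(10)])  # collinear
    with pytest.raises(SingularFitError):
        fit_random_intercept(y, X, np.repeat(np.arange(5), 2))


# --- mixed-model regression over band powers --------------------------------

def _scores_powers_meta(rng, n=80, coef=-0.1, channel="Fz", band="theta"):
    subjects = [f"s{i:03d}" for i in range(n)]
    meta = pd.DataFrame({
        "subject_id": subjects,
        "sex": rng.choice(["male", "female"], n),
    })
    rows_p, rows_s = [], []
    raw_power = {}
    for s in subjects:
        base = np.exp(rng.normal(3.0, 0.5))
        u = 0.05 * rng.standard_normal()
        for ses, eye in (("ses-EO", "EO"), ("ses-EC", "EC")):
            p = base * np.exp(0.1 * rng.standard_normal())
            raw_power[(s, ses)] = p
            rows_p.append((s, ses, eye, channel, band, p))
    # z-score across all rows so the planted coefficient is on the fitted scale
    vals = np.array([raw_power[k] for k in raw_power])
    z = (vals - vals.mean()) / vals.std()
    for (s, ses), zi in zip(raw_power, z):
        u = 0.0
        score = 0.5 + coef * zi + 0.03 * rng.standard_normal()
        rows_s.append((s, ses, score))
    powers = pd.DataFrame(rows_p, columns=["subject_id", "session_id", "eye_state", "channel", "band", "power"])
    scores = pd.DataFrame(rows_s, columns=["subject_id", "session_id", "score"])
    return scores, powers, meta


def test_fit_recovers_planted_coefficient(rng):
    scores, powers, meta = _scores_powers_meta(rng, n=200, coef=-0.1)
    fe = fit_mixed_model(scores, powers, ("Fz", "theta"), meta)
    assert fe["power"] == pytest.approx(-0.1, abs=0.03)


def test_constant_predictor_flagged_singular(rng):
    scores, powers, meta = _scores_powers_meta(rng, n=30)
    powers["power"] = 5.0
    fe = fit_mixed_model(scores, powers, ("Fz", "theta"), meta)
    assert fe["singular"] and fe["power"] == 0.0


def test_bootstrap_regression_recovers_effect_and_guards_nboot(rng):
    scores, powers, meta = _scores_powers_meta(rng, n=120, coef=-0.1)
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_regression(scores, powers, [("Fz", "theta")], meta, n_boot=10)
    res = bootstrap_regression(scores, powers, [("Fz", "theta")], meta, n_boot=120, seed=0)[0]
    assert res.significant and res.ci_high < 0
    assert res.coef_mean == pytest.approx(-0.1, abs=0.03)
    assert res.significant == (not (res.ci_low <= 0.0 <= res.ci_high))


def test_coefficient_invariant_to_uv_rescaling(rng):
    scores, powers, meta = _scores_powers_meta(rng, n=80, coef=-0.08)
    res1 = fit_mixed_model(scores, powers, ("Fz", "theta"), meta)
    powers2 = powers.assign(power=powers.power * 1e3)  # µV² -> nV² style rescale
    res2 = fit_mixed_model(scores, powers2, ("Fz", "theta"), meta)
    assert res1["power"] == pytest.approx(res2["power"], rel=1e-6)


def test_sex_coefficient_null_when_sex_is_permuted(rng):
    hits = 0
    for rep in range(10):
        scores, powers, meta = _scores_powers_meta(rng, n=60, coef=0.0)
        res = bootstrap_regression(scores, powers, [("Fz", "theta")], meta,
                                   n_boot=100, seed=rep)[0]
        fe = res.fixed_effects
        # permuted/random sex: its mean coefficient should hover near zero
        hits += abs(fe["sex"]) > 0.05
    assert hits <= 3
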