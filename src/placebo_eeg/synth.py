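"""Synthetic resting-state EEG cohorts with planted placebo-response structure.

The generator emulates the statistical skeleton the downstream pipeline
assumes: 19-channel 10-20 recordings built from 1/f background noise plus
band-limited oscillators, an eyes-closed alpha excess, class-dependent theta
(Fz, Cz, F8, C3) and lower-beta (F3, F4) amplitude shifts, a sex effect on
responder log-odds, an age-responder link, behavioural covariates with
tunable correlation to the label, and injectable artifacts matching each
rejection rule.  It makes no attempt at ERP morphology, volume conduction or
forward modelling — it exists so every pipeline stage has a recoverable
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import signal as sps

from .core import CANONICAL_CHANNELS, ARTIFACT_RULES, Recording

#: Channels carrying the class-dependent theta shift.
THETA_SHIFT_CHANNELS = ("Fz", "Cz", "F8", "C3")
#: Channels carrying the class-dependent lower-beta shift.
BETA_LOW_SHIFT_CHANNELS = ("F3", "F4")

#: Oscillator passbands, Hz.
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta_low": (13.0, 20.0),
    "beta_high": (20.0, 30.0),
}

# Baseline oscillator RMS amplitudes (µV) and the between-subject coefficient
# of variation that defines one "standardized" unit of planted shift.
_BASE_AMP = {"theta": 5.0, "alpha": 8.0, "beta_low": 4.0, "beta_high": 2.5}
_AMP_CV = 0.25
_ALPHA_EC_GAIN = 1.6  # eyes-closed alpha excess
_PINK_RMS = 12.0  # µV, 1/f background

#: Posterior-dominant alpha topography (resting alpha is occipital-maximal).
_ALPHA_TOPOGRAPHY = {"Fp": 0.5, "F": 0.6, "T": 0.8, "C": 0.8, "P": 1.1, "O": 1.4}


def _alpha_scale(channel: str) -> float:
    for prefix in ("Fp", "F", "T", "C", "P", "O"):
        if channel.startswith(prefix) and (prefix != "F" or not channel.startswith("Fp")):
            return _ALPHA_TOPOGRAPHY[prefix]
    return 1.0  # pragma: no cover - all 10-20 names match a prefix


class ConfigurationError(ValueError):
    """A cohort-spec field is out of range; the message names the field."""


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Effect sizes are standardized amplitude shifts (units of the
    between-subject amplitude SD); negative values plant the
    lower-oscillatory-power-in-responders direction.
    """

    n_subjects: int = 60
    responder_rate: float = 0.4
    sessions_per_subject: int = 1  # per eye state
    duration_s: float = 120.0
    native_rate_hz: float = 250.0
    effect_theta: float = -0.5
    effect_beta_low: float = -0.5
    sex_effect: float = -0.5  # male shift in responder log-odds
    age_slope: float = -1.0  # log-odds per SD of age
    artifact_rates: dict = field(default_factory=lambda: {r: 0.05 for r in ARTIFACT_RULES})
    covariate_effects: dict = field(
        default_factory=lambda: {"extraversion": 0.2, "reaction_time": -0.2}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be a positive integer")
        if not 0.0 <= self.responder_rate <= 1.0:
            raise ConfigurationError("responder_rate must lie in [0, 1]")
        if self.sessions_per_subject < 1:
            raise ConfigurationError("sessions_per_subject must be a positive integer")
        if self.duration_s < 16.0:
            raise ConfigurationError("duration_s must be at least 16 s (one segment)")
        if self.native_rate_hz <= 200.0:
            raise ConfigurationError("native_rate_hz must exceed 200 Hz (0.5-100 Hz passband)")
        for rule, rate in self.artifact_rates.items():
            if rule not in ARTIFACT_RULES:
                raise ConfigurationError(
                    f"artifact_rates has unknown rule {rule!r}; valid: {ARTIFACT_RULES}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"artifact_rates[{rule!r}] must lie in [0, 1]")


@dataclass
class SubjectRecord:
    """Metadata row for one synthetic participant.

    ``remission`` encodes the binary endpoint (depression-scale score <= 7)
    used as the training label; for placebo-arm subjects it is the
    placebo-responder label.
    """

    subject_id: str
    age_years: float
    sex: str  # "male" / "female"
    arm: str  # "placebo" / "drug"
    baseline_score: int
    endpoint_score: int
    remission: bool
    covariates: dict

    def __post_init__(self) -> None:
        if self.remission != (self.endpoint_score <= 7):
            raise ValueError("remission flag must equal (endpoint_score <= 7)")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, chi: float = 1.0) -> np.ndarray:
    """1/f^chi noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-chi / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian oscillation, unit RMS."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    pad = int(2 * fs)
    x = sps.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    return x / x.std()


def _subject_amplitudes(rng: np.random.Generator, remission: bool, spec: CohortSpec) -> dict:
    """Per-subject, per-channel oscillator RMS amplitudes (µV)."""
    shift_for = {
        "theta": (spec.effect_theta, THETA_SHIFT_CHANNELS),
        "beta_low": (spec.effect_beta_low, BETA_LOW_SHIFT_CHANNELS),
    }
    amps: dict = {}
    for band, base in _BASE_AMP.items():
        g = rng.standard_normal()  # between-subject variation, shared across channels
        per_channel = {}
        for ch in CANONICAL_CHANNELS:
            jitter = 0.03 * rng.standard_normal()
            factor = 1.0 + _AMP_CV * g + jitter
            effect, targets = shift_for.get(band, (0.0, ()))
            if remission and ch in targets:
                factor += _AMP_CV * effect
            topo = _alpha_scale(ch) if band == "alpha" else 1.0
            per_channel[ch] = base * topo * max(0.1, factor)
        amps[band] = per_channel
    return amps


def _render_recording(
    seed_seq: np.random.SeedSequence,
    subject_id: str,
    session_id: str,
    eye_state: str,
    amps: dict,
    pink_rms: float,
    spec: CohortSpec,
) -> Recording:
    rng = np.random.default_rng(seed_seq)
    n = int(round(spec.duration_s * spec.native_rate_hz))
    fs = spec.native_rate_hz
    data = np.empty((len(CANONICAL_CHANNELS), n))
    for i, ch in enumerate(CANONICAL_CHANNELS):
        x = pink_rms * _pink_noise(rng, n, fs)
        for band, (lo, hi) in BANDS.items():
            amp = amps[band][ch]
            if band == "alpha" and eye_state == "EC":
                amp *= _ALPHA_EC_GAIN
            x = x + amp * _band_noise(rng, n, fs, (lo, hi))
        data[i] = x
    return Recording(
        subject_id=subject_id, session_id=session_id, eye_state=eye_state,
        rate_hz=fs, channels=CANONICAL_CHANNELS, data=data,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], list[SubjectRecord]]:
    """Generate recordings (one EO + one EC per subject per session) and metadata.

    Deterministic: identical ``spec`` (including ``seed``) reproduces the
    cohort bit for bit.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])

    n = spec.n_subjects
    ages = meta_rng.uniform(18.0, 65.0, size=n)
    z_age = (ages - 41.5) / (47.0 / np.sqrt(12.0))  # U(18,65) moments
    male = meta_rng.random(n) < 0.5
    arm = np.where(meta_rng.random(n) < 0.5, "placebo", "drug")

    base_logit = np.log(spec.responder_rate / (1.0 - spec.responder_rate)) if 0 < spec.responder_rate < 1 else (
        np.inf if spec.responder_rate >= 1 else -np.inf
    )
    logits = base_logit + spec.sex_effect * male + spec.age_slope * z_age
    p = 1.0 / (1.0 + np.exp(-logits))
    remission = meta_rng.random(n) < p

    baseline = np.clip(np.rint(meta_rng.normal(18.0, 3.0, size=n)), 14, 30).astype(int)
    endpoint = np.where(
        remission,
        np.rint(meta_rng.uniform(2.0, 7.0, size=n)),
        np.clip(np.rint(meta_rng.normal(13.0, 3.0, size=n)), 8, 28),
    ).astype(int)

    # covariates correlated with the label at the configured strength
    y = remission.astype(float)
    y_sd = y.std()
    z_label = (y - y.mean()) / y_sd if y_sd > 0 else np.zeros(n)
    covariates: dict[str, np.ndarray] = {}
    for name, rho in spec.covariate_effects.items():
        rho = float(np.clip(rho, -0.999, 0.999))
        noise = meta_rng.standard_normal(n)
        covariates[name] = rho * z_label + np.sqrt(1.0 - rho**2) * noise

    subjects = [
        SubjectRecord(
            subject_id=f"sub-{i:04d}",
            age_years=float(ages[i]),
            sex="male" if male[i] else "female",
            arm=str(arm[i]),
            baseline_score=int(baseline[i]),
            endpoint_score=int(endpoint[i]),
            remission=bool(remission[i]),
            covariates={k: float(v[i]) for k, v in covariates.items()},
        )
        for i in range(n)
    ]

    recordings: list[Recording] = []
    rules = list(ARTIFACT_RULES)
    for i, subj in enumerate(subjects):
        amp_seq, *_ = np.random.SeedSequence((spec.seed, 1, i)).spawn(1)
        amp_rng = np.random.default_rng(amp_seq)
        amps = _subject_amplitudes(amp_rng, subj.remission, spec)
        pink_rms = _PINK_RMS * max(0.5, 1.0 + 0.15 * amp_rng.standard_normal())
        for sess in range(spec.sessions_per_subject):
            for eye_code, eye in enumerate(("EO", "EC")):
                seq = np.random.SeedSequence((spec.seed, 2, i, sess, eye_code))
                rec = _render_recording(
                    seq, subj.subject_id, f"ses-{sess:02d}-{eye}", eye, amps, pink_rms, spec
                )
                art_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 3, i, sess, eye_code)))
                for rule in rules:
                    rate = spec.artifact_rates.get(rule, 0.0)
                    if rate > 0 and art_rng.random() < rate:
                        max_start = spec.duration_s - _ARTIFACT_DURATION[rule] - 1.0
                        at = float(art_rng.uniform(1.0, max(1.0, max_start)))
                        rec = inject_artifact(rec, rule, at, rng=art_rng)
                recordings.append(rec)
    return recordings, subjects


# --- artifact injection -----------------------------------------------------

#: seconds of recording each injected event occupies
_ARTIFACT_DURATION = {
    "extreme_voltage": 1.0,
    "muscle": 1.2,
    "abrupt_transition": 1.0,
    "kurtosis": 1.0,
    "blink": 10.0,
    "bridging": 0.0,  # whole recording
}

_ARTIFACT_CHANNEL = {
    "extreme_voltage": "Pz",
    "muscle": "T7",
    "abrupt_transition": "F8",  # low-alpha channel so the step clears the amplitude baseline
    "kurtosis": "F7",  # frontal: away from the posterior alpha that dilutes kurtosis
}


def inject_artifact(
    rec: Recording, rule: str, at_s: float, rng: np.random.Generator | None = None
) -> Recording:
    """Return a copy of ``rec`` with one synthetic event of the named class.

    Event shapes are chosen so each class trips its own detection rule and
    stays below the thresholds of the other five (e.g. the extreme-voltage
    event is a smooth 250 µV hump, not a step, so it leaves first differences
    small).
    """
    if rule not in ARTIFACT_RULES:
        raise ValueError(f"unknown artifact rule {rule!r}; valid ids: {', '.join(ARTIFACT_RULES)}")
    dur = _ARTIFACT_DURATION[rule]
    if rule != "bridging" and at_s + dur > rec.duration_s + 1e-9:
        raise ValueError(
            f"artifact of {dur} s at {at_s} s exceeds recording duration {rec.duration_s} s"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    out = rec.copy()
    fs = rec.rate_hz
    i0 = int(round(at_s * fs))

    if rule == "extreme_voltage":
        # smooth half-sine hump, peak 350 µV over 0.4 s: slow enough to keep
        # first differences small, fast enough to survive the 0.5 Hz high-pass
        width = int(0.4 * fs)
        hump = 350.0 * np.sin(np.linspace(0.0, np.pi, width))
        ch = out.channel_index(_ARTIFACT_CHANNEL[rule])
        out.data[ch, i0 : i0 + width] += hump
    elif rule == "muscle":
        # 75-95 Hz burst, 7 µV RMS, 1.2 s
        width = int(dur * fs)
        burst = 7.0 * _band_noise(rng, width, fs, (75.0, 95.0))
        ch = out.channel_index(_ARTIFACT_CHANNEL[rule])
        out.data[ch, i0 : i0 + width] += burst
    elif rule == "abrupt_transition":
        # +100 µV step held for 1 s: two single-sample jumps
        width = int(dur * fs)
        ch = out.channel_index(_ARTIFACT_CHANNEL[rule])
        out.data[ch, i0 : i0 + width] += 100.0
    elif rule == "kurtosis":
        # sparse alternating-sign Gaussian spikes: sparse + large keeps
        # window kurtosis high; the step rule ignores them (no level shift)
        ch = out.channel_index(_ARTIFACT_CHANNEL[rule])
        t = np.arange(int(dur * fs)) / fs
        spike = np.zeros_like(t)
        for center in (0.2, 0.5, 0.8):
            spike += 130.0 * np.exp(-0.5 * ((t - center) / 0.010) ** 2)
        out.data[ch, i0 : i0 + len(t)] += spike
    elif rule == "blink":
        # five positive frontal humps over ~10 s on Fp1 and Fp2
        t = np.arange(int(dur * fs)) / fs
        train = np.zeros_like(t)
        for k in range(5):
            center = 1.0 + 2.0 * k
            train += 70.0 * np.exp(-0.5 * ((t - center) / 0.15) ** 2)
        for name, gain in (("Fp1", 1.0), ("Fp2", 0.9)):
            ch = out.channel_index(name)
            out.data[ch, i0 : i0 + len(t)] += gain * train
    elif rule == "bridging":
        # duplicate P3 into P4 with sub-µV residual noise, whole recording
        src = out.channel_index("P3")
        dst = out.channel_index("P4")
        out.data[dst] = out.data[src] + 0.05 * rng.standard_normal(out.n_samples)
    return out


# --- on-disk cohort ---------------------------------------------------------

def write_cohort(
    recordings: Iterable[Recording],
    subjects: Iterable[SubjectRecord],
    out_dir,
) -> None:
    """Write one EDF per session plus a metadata CSV (``metadata.csv``)."""
    import pandas as pd
    from pathlib import Path

    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_edf(rec, out_dir / f"{rec.subject_id}_{rec.session_id}.edf")
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id, "age_years": s.age_years, "sex": s.sex,
            "arm": s.arm, "baseline_score": s.baseline_score,
            "endpoint_score": s.endpoint_score, "remission": int(s.remission),
        }
        row.update(s.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "metadata.csv", index=False)


def read_metadata(path) -> list[SubjectRecord]:
    """Read a metadata CSV written by :func:`write_cohort`."""
    import pandas as pd

    df = pd.read_csv(path)
    fixed = {"subject_id", "age_years", "sex", "arm", "baseline_score", "endpoint_score", "remission"}
    return [
        SubjectRecord(
            subject_id=str(r["subject_id"]), age_years=float(r["age_years"]),
            sex=str(r["sex"]), arm=str(r["arm"]),
            baseline_score=int(r["baseline_score"]), endpoint_score=int(r["endpoint_score"]),
            remission=bool(int(r["remission"])),
            covariates={k: float(r[k]) for k in df.columns if k not in fixed},
        )
        for _, r in df.iterrows()
    ]
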