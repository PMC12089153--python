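"""Recording cleanup: filtering, ocular correction, artifact rules, segmentation.

The cleaning contract: band-pass 0.5-100 Hz with 50/60 Hz notches (zero
phase), ocular correction (ICA or a regression fallback), six independent
artifact-detection rules, then segmentation into 16-s windows with 15-s
overlap resampled to 125 Hz — every kept segment is exactly
[19 channels x 2000 samples].  Artifact timestamps are carried in seconds so
rejection is independent of the sampling rate at which rules ran.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .core import (
    ARTIFACT_RULES,
    CANONICAL_CHANNELS,
    N_CHANNELS,
    SEGMENT_RATE_HZ,
    SEGMENT_SAMPLES,
    SEGMENT_SECONDS,
    SEGMENT_STRIDE_S,
    ArtifactReport,
    ArtifactWindow,
    Recording,
    SegmentSet,
)

__all__ = [
    "ArtifactConfig", "bandpass_notch", "ocular_correct", "detect_artifacts",
    "segment", "map_montage", "preprocess_recording",
]


# --- filtering --------------------------------------------------------------

def bandpass_notch(
    rec: Recording,
    low_hz: float = 0.5,
    high_hz: float = 100.0,
    notch_hz: tuple[float, ...] = (50.0, 60.0),
) -> Recording:
    """Zero-phase band-pass (4th-order Butterworth) plus mains notches.

    Filtering runs at the native rate and therefore requires a sampling rate
    comfortably above twice the upper band edge; resampling to 125 Hz happens
    only afterwards, at segmentation.
    """
    if rec.rate_hz <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {rec.rate_hz} Hz too low for a {high_hz} Hz band edge; "
            "filtering precedes resampling and must run at the native rate"
        )
    out = rec.copy()
    sos = sps.butter(4, (low_hz, high_hz), btype="bandpass", fs=rec.rate_hz, output="sos")
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    for f0 in notch_hz:
        b, a = sps.iirnotch(f0, Q=30.0, fs=rec.rate_hz)
        out.data = sps.filtfilt(b, a, out.data, axis=1)
    return out


# --- ocular correction ------------------------------------------------------

def _blink_reference(rec: Recording) -> np.ndarray:
    """Blink proxy: 0.5-4 Hz filtered mean of the frontal-polar channels."""
    frontal = [ch for ch in ("Fp1", "Fp2") if ch in rec.channels]
    if len(frontal) < 2:
        raise ValueError("regression ocular correction needs Fp1 and Fp2")
    ref = rec.data[[rec.channel_index(c) for c in frontal]].mean(axis=0)
    sos = sps.butter(2, (0.5, 4.0), btype="bandpass", fs=rec.rate_hz, output="sos")
    return sps.sosfiltfilt(sos, ref)


def ocular_correct(rec: Recording, method: str = "regression") -> Recording:
    """Attenuate blink transients.

    ``regression`` detects blink events on a frontal 0.5-4 Hz reference and
    subtracts the per-channel regression on the event-masked reference, so a
    blink-free recording passes through essentially unchanged.  ``ica``
    delegates to MNE's ICA with automatic frontal-artifact component
    selection and falls back to regression (with a warning) on recordings
    shorter than 60 s.  ``none`` is the identity.
    """
    if method == "none":
        return rec.copy()
    if method not in ("ica", "regression"):
        raise ValueError(f"unknown ocular-correction method {method!r}")
    if method == "ica":
        if rec.duration_s < 60.0:
            warnings.warn(
                "recording shorter than 60 s: ICA unreliable, falling back to regression",
                stacklevel=2,
            )
            return ocular_correct(rec, "regression")
        return _ocular_ica(rec)

    slow = _blink_reference(rec)
    sd = 1.4826 * np.median(np.abs(slow - np.median(slow))) + 1e-12
    mask = np.abs(slow) > 4.0 * sd
    if mask.sum() < 3:
        return rec.copy()
    # dilate the event mask by 300 ms so blink flanks are covered, then use
    # the raw (unfiltered) frontal mean inside the mask as the template: the
    # band-filtered trace distorts blink shape and undercorrects the peak
    width = max(1, int(0.3 * rec.rate_hz))
    mask = np.convolve(mask.astype(float), np.ones(2 * width + 1), mode="same") > 0
    frontal = [rec.channel_index(c) for c in ("Fp1", "Fp2")]
    raw_ref = rec.data[frontal].mean(axis=0)
    raw_ref = raw_ref - np.median(raw_ref)
    ref_masked = np.where(mask, raw_ref, 0.0)
    out = rec.copy()
    denom = float(ref_masked @ ref_masked)
    if denom <= 0:
        return out
    beta = (out.data @ ref_masked) / denom
    out.data = out.data - beta[:, None] * ref_masked[None, :]
    return out


def _ocular_ica(rec: Recording) -> Recording:
    import mne

    info = mne.create_info(list(rec.channels), rec.rate_hz, ch_types="eeg", verbose="error")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    raw.set_montage("standard_1020", on_missing="ignore", verbose="error")
    n_comp = min(15, len(rec.channels) - 1)
    ica = mne.preprocessing.ICA(n_components=n_comp, random_state=0, max_iter="auto", verbose="error")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(raw.copy().filter(1.0, None, verbose="error"), verbose="error")
        eog_idx, _ = ica.find_bads_eog(raw, ch_name=["Fp1", "Fp2"], verbose="error")
    ica.exclude = eog_idx
    cleaned = ica.apply(raw.copy(), verbose="error")
    out = rec.copy()
    out.data = cleaned.get_data() * 1e6
    return out


# --- artifact rules ---------------------------------------------------------

@dataclass
class ArtifactConfig:
    """Thresholds for the six rejection rules.

    Rules run independently; disabling one (``enabled``) never changes
    another's report.  Scan granularity: 1-s sliding windows for muscle,
    abrupt-transition context, kurtosis and blink; sample level for extreme
    voltage; whole recording for bridging.
    """

    extreme_voltage_uv: float = 200.0
    muscle_band: tuple[float, float] = (75.0, 95.0)
    muscle_z: float = 3.0
    muscle_ratio_floor: float = 4.0  # minimum band-power ratio vs recording median
    abrupt_sd: float = 2.0  # first-difference threshold: mean(|x|) + k*SD(x)
    kurtosis_excess: float = 4.0
    blink_peak_factor: float = 4.0  # peak height vs robust channel SD
    blink_min_count: int = 3  # matches within a 16-s span
    bridging_var_uv2: float = 0.5
    window_s: float = 1.0
    enabled: tuple[str, ...] = ARTIFACT_RULES


def _window_starts(n_samples: int, fs: float, window_s: float) -> np.ndarray:
    w = int(round(window_s * fs))
    return np.arange(0, n_samples - w + 1, w)


def _detect_extreme_voltage(rec: Recording, cfg: ArtifactConfig) -> list[ArtifactWindow]:
    out = []
    fs = rec.rate_hz
    for ci, ch in enumerate(rec.channels):
        bad = np.abs(rec.data[ci]) > cfg.extreme_voltage_uv
        if not bad.any():
            continue
        # merge exceedances into 1-s-padded windows
        idx = np.flatnonzero(bad)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > fs) + 1)
        for grp in splits:
            out.append(ArtifactWindow(
                start_s=max(0.0, grp[0] / fs - 0.5),
                end_s=min(rec.duration_s, grp[-1] / fs + 0.5),
                rule_id="extreme_voltage", channel=ch,
                score=float(np.abs(rec.data[ci, grp]).max()),
            ))
    return out


def _detect_muscle(rec: Recording, cfg: ArtifactConfig) -> list[ArtifactWindow]:
    fs = rec.rate_hz
    w = int(round(cfg.window_s * fs))
    starts = _window_starts(rec.n_samples, fs, cfg.window_s)
    lo, hi = cfg.muscle_band
    sos = sps.butter(4, (lo, min(hi, 0.45 * fs)), btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, rec.data, axis=1)
    out = []
    # median-based band power: robust to impulsive transients (step edges,
    # spikes) whose filter ringing would otherwise mimic a sustained burst
    gauss_consistency = 0.4549
    for ci, ch in enumerate(rec.channels):
        power = np.array([
            np.median(band[ci, s : s + w] ** 2) / gauss_consistency for s in starts
        ])
        logp = np.log(power + 1e-12)
        med = np.median(logp)
        scale = 1.4826 * np.median(np.abs(logp - med)) + 1e-12
        z = (logp - med) / scale
        ratio = power / (np.median(power) + 1e-12)
        for s, zi, ri in zip(starts, z, ratio):
            if zi > cfg.muscle_z and ri > cfg.muscle_ratio_floor:
                out.append(ArtifactWindow(s / fs, s / fs + cfg.window_s, "muscle", ch, float(zi)))
    return out


def _detect_abrupt(rec: Recording, cfg: ArtifactConfig) -> list[ArtifactWindow]:
    """Step detector: a sample-to-sample jump exceeding the recording
    amplitude baseline (mean |x| + k SD) that also persists as a level shift
    over the surrounding 300 ms, so isolated spikes do not qualify."""
    fs = rec.rate_hz
    half = max(1, int(0.3 * fs))
    out = []
    for ci, ch in enumerate(rec.channels):
        x = rec.data[ci]
        thr = np.mean(np.abs(x)) + cfg.abrupt_sd * np.std(x)
        cand = np.flatnonzero(np.abs(np.diff(x)) > thr)
        jumps = []
        for i in cand:
            lo, hi = max(0, i - half), min(len(x), i + 1 + half)
            shift = x[i + 1 : hi].mean() - x[lo : i + 1].mean()
            if abs(shift) > 0.5 * thr:
                jumps.append(i)
        jumps = np.asarray(jumps)
        if jumps.size == 0:
            continue
        splits = np.split(jumps, np.flatnonzero(np.diff(jumps) > fs) + 1)
        for grp in splits:
            out.append(ArtifactWindow(
                start_s=max(0.0, grp[0] / fs - 0.5),
                end_s=min(rec.duration_s, (grp[-1] + 1) / fs + 0.5),
                rule_id="abrupt_transition", channel=ch,
                score=float(np.abs(np.diff(x))[grp].max() / thr),
            ))
    return out


def _detect_kurtosis(rec: Recording, cfg: ArtifactConfig) -> list[ArtifactWindow]:
    """Spikiness: excess kurtosis in 2-s windows.  The doubled window keeps
    the estimator tight enough that Gaussian background stays near 0 while
    spike trains land far above the threshold; steps read as bimodal
    (negative excess) and never qualify."""
    fs = rec.rate_hz
    win_s = 2.0 * cfg.window_s
    w = int(round(win_s * fs))
    starts = _window_starts(rec.n_samples, fs, win_s)
    out = []
    for ci, ch in enumerate(rec.channels):
        for s in starts:
            seg = rec.data[ci, s : s + w]
            k = float(spstats.kurtosis(seg, fisher=True, bias=True))
            if k > cfg.kurtosis_excess:
                out.append(ArtifactWindow(s / fs, s / fs + win_s, "kurtosis", ch, k))
    return out


def _detect_blink(rec: Recording, cfg: ArtifactConfig) -> list[ArtifactWindow]:
    """Persistent residual blinks: >= blink_min_count frontal positive
    transients above blink_peak_factor x robust SD inside one 16-s span."""
    fs = rec.rate_hz
    out = []
    for name in ("Fp1", "Fp2"):
        if name not in rec.channels:
            continue
        x = rec.data[rec.channel_index(name)]
        sos = sps.butter(2, (0.5, 4.0), btype="bandpass", fs=fs, output="sos")
        slow = sps.sosfiltfilt(sos, x)
        sd = 1.4826 * np.median(np.abs(slow - np.median(slow))) + 1e-12
        peaks, _ = sps.find_peaks(slow, height=cfg.blink_peak_factor * sd, distance=int(0.3 * fs))
        if peaks.size < cfg.blink_min_count:
            continue
        times = peaks / fs
        span = SEGMENT_SECONDS
        for i in range(len(times)):
            j = np.searchsorted(times, times[i] + span, side="right")
            if j - i >= cfg.blink_min_count:
                out.append(ArtifactWindow(
                    start_s=max(0.0, times[i] - 0.5),
                    end_s=min(rec.duration_s, times[j - 1] + 0.5),
                    rule_id="blink", channel=name, score=float(j - i),
                ))
                break  # one span per channel is enough to reject the stretch
    return out


def _detect_bridging(rec: Recording, cfg: ArtifactConfig) -> list[ArtifactWindow]:
    out = []
    n = len(rec.channels)
    for i in range(n):
        for j in range(i + 1, n):
            ed = float(np.var(rec.data[i] - rec.data[j]))
            if ed < cfg.bridging_var_uv2:
                out.append(ArtifactWindow(
                    0.0, rec.duration_s, "bridging",
                    channel=f"{rec.channels[i]}-{rec.channels[j]}", score=ed,
                ))
    return out


_RULE_DETECTORS = {
    "muscle": _detect_muscle,
    "extreme_voltage": _detect_extreme_voltage,
    "abrupt_transition": _detect_abrupt,
    "kurtosis": _detect_kurtosis,
    "blink": _detect_blink,
    "bridging": _detect_bridging,
}


def detect_artifacts(rec: Recording, cfg: ArtifactConfig | None = None) -> ArtifactReport:
    """Run every enabled rule independently and pool the flagged windows."""
    cfg = cfg or ArtifactConfig()
    windows: list[ArtifactWindow] = []
    for rule in ARTIFACT_RULES:
        if rule in cfg.enabled:
            windows.extend(_RULE_DETECTORS[rule](rec, cfg))
    return ArtifactReport(windows=windows)


# --- segmentation -----------------------------------------------------------

def segment(rec: Recording, report: ArtifactReport | None = None) -> SegmentSet:
    """Resample to 125 Hz and cut 16-s windows with a 1-s hop.

    Windows are half-open ``[start, start+16)`` at integer-second starts; any
    window overlapping a flagged artifact window (in seconds, so independent
    of rate) is rejected and annotated with the responsible rule ids.
    """
    if tuple(rec.channels) != CANONICAL_CHANNELS:
        raise ValueError("segment expects the canonical 19-channel montage; run map_montage first")
    if rec.duration_s < SEGMENT_SECONDS:
        warnings.warn(
            f"recording of {rec.duration_s:.1f} s is shorter than one {SEGMENT_SECONDS:.0f}-s "
            "segment; returning an empty SegmentSet", stacklevel=2,
        )
        return SegmentSet.empty()
    report = report or ArtifactReport()

    frac = Fraction(SEGMENT_RATE_HZ / rec.rate_hz).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)

    n_seg = int(np.floor((rec.duration_s - SEGMENT_SECONDS) / SEGMENT_STRIDE_S)) + 1
    segs = np.empty((n_seg, N_CHANNELS, SEGMENT_SAMPLES))
    index, kept, reasons = [], [], []
    for k in range(n_seg):
        start_s = k * SEGMENT_STRIDE_S
        i0 = int(round(start_s * SEGMENT_RATE_HZ))
        segs[k] = data[:, i0 : i0 + SEGMENT_SAMPLES]
        hit = sorted({
            w.rule_id for w in report.windows
            if start_s < w.end_s and w.start_s < start_s + SEGMENT_SECONDS
        })
        index.append({
            "subject_id": rec.subject_id, "session_id": rec.session_id,
            "eye_state": rec.eye_state, "start_s": float(start_s),
        })
        kept.append(not hit)
        reasons.append(tuple(hit))
    return SegmentSet(data=segs, index=index, kept_mask=np.array(kept), reject_reason=reasons)


# --- montage ----------------------------------------------------------------

def map_montage(rec: Recording, table: dict[str, str] | None = None) -> Recording:
    """Reduce/reorder channels onto the canonical 19-name 10-20 montage.

    ``table`` maps source channel names to 10-20 target names (for example a
    high-density-net conversion table).  ``None`` means the identity mapping.
    Raises if any canonical target cannot be filled, listing the gaps.
    """
    table = table if table is not None else {c: c for c in rec.channels}
    target_to_source: dict[str, str] = {}
    for src, dst in table.items():
        if dst in CANONICAL_CHANNELS and src in rec.channels:
            target_to_source.setdefault(dst, src)
    missing = [c for c in CANONICAL_CHANNELS if c not in target_to_source]
    if missing:
        raise ValueError(f"montage table does not cover target channel(s): {', '.join(missing)}")
    rows = [rec.channel_index(target_to_source[c]) for c in CANONICAL_CHANNELS]
    out = rec.copy()
    out.channels = CANONICAL_CHANNELS
    out.data = rec.data[rows].copy()
    return out


# --- convenience: full per-recording chain ---------------------------------

def preprocess_recording(
    rec: Recording,
    montage_table: dict[str, str] | None = None,
    ocular_method: str = "regression",
    cfg: ArtifactConfig | None = None,
) -> SegmentSet:
    """map_montage -> bandpass_notch -> ocular_correct -> detect -> segment."""
    rec = map_montage(rec, montage_table)
    rec = bandpass_notch(rec)
    rec = ocular_correct(rec, ocular_method)
    report = detect_artifacts(rec, cfg)
    return segment(rec, report)
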