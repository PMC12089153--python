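"""Filtering, artifact rules, segmentation and montage mapping."""

import numpy as np
import pytest

from placebo_eeg.core import (
    ARTIFACT_RULES,
    CANONICAL_CHANNELS,
    ArtifactReport,
    ArtifactWindow,
    Recording,
)
from placebo_eeg.preprocess import (
    ArtifactConfig,
    bandpass_notch,
    detect_artifacts,
    map_montage,
    ocular_correct,
    segment,
)
from placebo_eeg.synth import inject_artifact


def _tone(freq, fs=250.0, dur=30.0):
    t = np.arange(int(dur * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (19, 1))
    return Recording("s0", "A", "EO", fs, CANONICAL_CHANNELS, data)


def _fft_amp(x, freq, fs):
    spec = np.abs(np.fft.rfft(x)) / len(x) * 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return spec[np.argmin(np.abs(f - freq))]


@pytest.mark.parametrize("freq,lo,hi", [(10.0, 0.95, 1.05), (50.0, 0.0, 0.1), (60.0, 0.0, 0.1)])
def test_bandpass_notch_gain(freq, lo, hi):
    rec = _tone(freq)
    out = bandpass_notch(rec)
    ratio = _fft_amp(out.data[0], freq, 250.0) / _fft_amp(rec.data[0], freq, 250.0)
    assert lo <= ratio <= hi


def test_bandpass_zero_in_zero_out():
    rec = Recording("s0", "A", "EO", 250.0, CANONICAL_CHANNELS, np.zeros((19, 5000)))
    assert np.allclose(bandpass_notch(rec).data, 0.0)


def test_bandpass_requires_rate_above_nyquist():
    rec = _tone(10.0, fs=150.0)
    with pytest.raises(ValueError, match="native rate"):
        bandpass_notch(rec)


# --- ocular correction ------------------------------------------------------

def test_regression_removes_injected_blinks(clean_recording):
    from scipy.signal import butter, sosfiltfilt

    rec = inject_artifact(clean_recording, "blink", 5.0)
    corrected = ocular_correct(rec, "regression")
    fp1 = rec.channel_index("Fp1")
    window = slice(int(5 * 250), int(15 * 250))
    sos = butter(2, (0.5, 4.0), btype="bandpass", fs=250.0, output="sos")
    slow_before = sosfiltfilt(sos, rec.data[fp1])[window]
    slow_after = sosfiltfilt(sos, corrected.data[fp1])[window]
    assert np.abs(slow_after).max() <= 0.5 * np.abs(slow_before).max()


def test_blink_free_recording_nearly_unchanged(clean_recording):
    for method in ("regression", "none"):
        out = ocular_correct(clean_recording, method)
        rms_ratio = out.data.std() / clean_recording.data.std()
        assert 0.9 <= rms_ratio <= 1.1
    np.testing.assert_array_equal(
        ocular_correct(clean_recording, "none").data, clean_recording.data
    )


def test_short_recording_ica_falls_back_with_warning(clean_recording):
    with pytest.warns(UserWarning, match="falling back"):
        out = ocular_correct(clean_recording, "ica")  # 20 s < 60 s
    assert out.data.shape == clean_recording.data.shape


# --- artifact rules ---------------------------------------------------------

def test_clean_recording_passes_all_rules(small_cohort):
    recordings, _ = small_cohort
    for rec in recordings[:4]:
        report = detect_artifacts(bandpass_notch(rec))
        assert len(report) == 0


@pytest.mark.parametrize("rule", ARTIFACT_RULES)
def test_each_injected_artifact_flags_its_rule_only(clean_recording, rule):
    rec = inject_artifact(clean_recording, rule, 6.0 if rule != "blink" else 8.0)
    report = detect_artifacts(bandpass_notch(rec))
    assert {w.rule_id for w in report.windows} == {rule}


def test_voltage_spike_location_and_threshold(clean_recording):
    rec = inject_artifact(clean_recording, "extreme_voltage", 5.0)
    report = detect_artifacts(bandpass_notch(rec))
    hits = report.by_rule("extreme_voltage")
    assert hits and any(w.start_s <= 5.4 <= w.end_s for w in hits)
    assert all(w.score > 200.0 for w in hits)


def test_bridging_entry_names_the_duplicated_pair(clean_recording):
    rec = inject_artifact(clean_recording, "bridging", 0.0)
    report = detect_artifacts(bandpass_notch(rec))
    hits = report.by_rule("bridging")
    assert len(hits) == 1 and hits[0].channel == "P3-P4"
    assert hits[0].score < 0.5


def test_muscle_band_power_in_injected_window(clean_recording):
    from scipy.signal import welch

    rec = inject_artifact(clean_recording, "muscle", 10.0)
    f = bandpass_notch(rec)
    ch = f.channel_index("T7")
    def band(x):
        freqs, psd = welch(x, fs=250.0, nperseg=250)
        sel = (freqs >= 75) & (freqs <= 95)
        return np.trapezoid(psd[sel], freqs[sel])

    win_power = band(f.data[ch, int(10 * 250) : int(11 * 250)])
    per_window = [band(f.data[ch, s : s + 250]) for s in range(0, f.n_samples - 249, 250)]
    assert win_power >= 5 * np.median(per_window)


def test_rule_independence_under_disabling(clean_recording):
    rec = inject_artifact(
        inject_artifact(clean_recording, "extreme_voltage", 5.0), "muscle", 12.0
    )
    filtered = bandpass_notch(rec)
    full = detect_artifacts(filtered)
    partial = detect_artifacts(filtered, ArtifactConfig(enabled=("extreme_voltage",)))
    assert partial.by_rule("extreme_voltage") == full.by_rule("extreme_voltage")
    assert len(partial.by_rule("muscle")) == 0


def test_unknown_rule_rejected():
    with pytest.raises(ValueError, match="bridging"):
        ArtifactReport(windows=[ArtifactWindow(0.0, 1.0, "nonsense")])


# --- segmentation -----------------------------------------------------------

def test_sixty_second_recording_gives_45_segments():
    rec = _tone(10.0, dur=60.0)
    ss = segment(rec, ArtifactReport())
    assert ss.n_segments == 45 and ss.n_kept == 45
    assert ss.data.shape == (45, 19, 2000)


def test_segment_dominant_frequency_preserved_after_resampling():
    rec = _tone(10.0, dur=30.0)
    ss = segment(rec, ArtifactReport())
    spec = np.abs(np.fft.rfft(ss.data[0, 0]))
    f = np.fft.rfftfreq(2000, 1 / 125.0)
    assert abs(f[np.argmax(spec[1:]) + 1] - 10.0) < 0.1


def test_full_cover_artifact_rejects_everything():
    rec = _tone(10.0, dur=60.0)
    report = ArtifactReport(windows=[ArtifactWindow(0.0, 60.0, "bridging")])
    ss = segment(rec, report)
    assert ss.n_segments == 45 and ss.n_kept == 0
    assert all(r == ("bridging",) for r in ss.reject_reason)


def test_rejection_is_monotone_in_artifact_windows():
    rec = _tone(10.0, dur=40.0)
    base = ArtifactReport(windows=[ArtifactWindow(5.0, 6.0, "muscle")])
    more = ArtifactReport(windows=base.windows + [ArtifactWindow(20.0, 21.0, "blink")])
    assert segment(rec, more).n_kept <= segment(rec, base).n_kept


def test_kept_mask_and_reject_reason_mutually_exclusive():
    rec = _tone(10.0, dur=40.0)
    report = ArtifactReport(windows=[ArtifactWindow(10.0, 11.0, "kurtosis")])
    ss = segment(rec, report)
    for kept, reasons in zip(ss.kept_mask, ss.reject_reason):
        assert kept == (len(reasons) == 0)


def test_too_short_recording_warns_and_returns_empty():
    rec = _tone(10.0, dur=10.0)
    with pytest.warns(UserWarning, match="shorter"):
        ss = segment(rec, ArtifactReport())
    assert ss.n_segments == 0


# --- montage ----------------------------------------------------------------

def test_identity_table_canonicalizes_order(clean_recording):
    shuffled_idx = list(range(19))[::-1]
    rec = Recording(
        "s0", "A", "EO", 250.0,
        tuple(clean_recording.channels[i] for i in shuffled_idx),
        clean_recording.data[shuffled_idx],
    )
    out = map_montage(rec)
    assert out.channels == CANONICAL_CHANNELS
    np.testing.assert_array_equal(out.data, clean_recording.data)


def test_larger_montage_reduced_to_19(clean_recording):
    extra = np.vstack([clean_recording.data, np.zeros((2, clean_recording.n_samples))])
    rec = Recording("s0", "A", "EO", 250.0,
                    clean_recording.channels + ("E901", "E902"), extra)
    table = {c: c for c in clean_recording.channels}
    out = map_montage(rec, table)
    assert len(out.channels) == 19 and out.data.shape[0] == 19


def test_missing_target_raises_naming_gap(clean_recording):
    table = {c: c for c in clean_recording.channels if c != "Pz"}
    with pytest.raises(ValueError, match="Pz"):
        map_montage(clean_recording, table)
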