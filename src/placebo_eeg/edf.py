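"""Minimal EDF reading and writing for multichannel EEG in microvolts.

Reading goes through :func:`mne.io.read_raw_edf`.  Writing is a small
self-contained EDF encoder (fixed-point 16-bit samples, one-second data
records), sufficient for round-tripping the synthetic cohorts produced by
:mod:`placebo_eeg.synth`.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .core import Recording

_HDR_FIELDS = 256  # bytes of fixed header


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write one recording as an EDF file (µV physical units).

    The sampling rate must be an integer (samples are packed in one-second
    data records); trailing samples that do not fill a whole record are
    zero-padded.
    """
    path = Path(path)
    fs = rec.rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(rec.channels)
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_sig, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    # physical range: symmetric, covers the data with headroom; rounded to
    # one decimal so the header string and the encoding scale agree exactly
    lim = np.ceil(max(1.0, float(np.abs(data).max()) * 1.05) * 10.0) / 10.0
    phys_min, phys_max = -lim, lim
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.rint((data - phys_min) * scale) + dig_min, dig_min, dig_max)
    digital = digital.astype("<i2")

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _pad("0", 8),
        _pad(f"{rec.subject_id} sex_X", 80),
        _pad(f"Startdate 01-JAN-2000 {rec.session_id} {rec.eye_state}", 80),
        _pad(start.strftime("%d.%m.%y"), 8),
        _pad(start.strftime("%H.%M.%S"), 8),
        _pad(str(_HDR_FIELDS * (1 + n_sig)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),  # record duration, seconds
        _pad(str(n_sig), 4),
    ])
    per_sig = b"".join([
        b"".join(_pad(ch, 16) for ch in rec.channels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in rec.channels),
        b"".join(_pad("uV", 8) for _ in rec.channels),
        b"".join(_pad(f"{phys_min:.1f}", 8) for _ in rec.channels),
        b"".join(_pad(f"{phys_max:.1f}", 8) for _ in rec.channels),
        b"".join(_pad(str(dig_min), 8) for _ in rec.channels),
        b"".join(_pad(str(dig_max), 8) for _ in rec.channels),
        b"".join(_pad("", 80) for _ in rec.channels),
        b"".join(_pad(str(fs), 8) for _ in rec.channels),
        b"".join(_pad("", 32) for _ in rec.channels),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        # data records: per record, all samples of signal 1, then signal 2, ...
        view = digital.reshape(n_sig, n_rec, fs)
        for r in range(n_rec):
            fh.write(view[:, r, :].tobytes())
    return path


def read_edf(
    path: str | Path,
    subject_id: str | None = None,
    session_id: str | None = None,
    eye_state: str | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in µV).

    Metadata not recoverable from the EDF header may be supplied explicitly;
    otherwise it is parsed from the recording-id field written by
    :func:`write_edf` or falls back to the file stem.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns Volts
    info_rec = ""
    try:
        with open(path, "rb") as fh:
            fh.seek(8 + 80)
            info_rec = fh.read(80).decode("ascii", errors="replace").strip()
    except OSError:
        pass
    tokens = info_rec.split()
    if eye_state is None:
        eye_state = next((t for t in tokens if t in ("EO", "EC")), "EO")
    if session_id is None:
        session_id = tokens[-2] if len(tokens) >= 2 and tokens[-1] in ("EO", "EC") else path.stem
    if subject_id is None:
        with open(path, "rb") as fh:
            fh.seek(8)
            subject_id = fh.read(80).decode("ascii", errors="replace").split()[0]
    return Recording(
        subject_id=subject_id,
        session_id=session_id,
        eye_state=eye_state,
        rate_hz=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        data=data_uv,
    )
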