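"""Recording ingestion and sliding-window epoching.

Recordings are cut into fixed-length windows (default 1 s, 50% overlap) that
carry the subject label; those windows are the classification samples. No
filtering or artifact handling is applied by default — an optional band-pass
hook exists but is off unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .montage import Montage, normalize_label

__all__ = ["Recording", "Epoch", "read_edf", "write_edf", "sliding_windows", "bandpass"]


@dataclass
class Recording:
    """Multi-channel recording: channels x samples, with sampling rate."""

    data: np.ndarray  # (channels, samples) float
    fs: float
    subject_id: str
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One window of a recording, labelled with its subject."""

    data: np.ndarray  # (channels, window samples)
    subject_id: str
    offset: int = 0  # start sample in the source recording
    condition: str = ""

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_edf(path: "str | Path", montage: Montage, subject_id: "str | None" = None) -> Recording:
    """Read an EDF file and order its channels to match the montage.

    Channel names are matched case-insensitively with trailing dots
    stripped (PhysioNet style). Raises if any montage channel is absent.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    by_key = {normalize_label(name): i for i, name in enumerate(raw.ch_names)}
    order = []
    for lab in montage.labels:
        key = normalize_label(lab)
        if key not in by_key:
            raise ValueError(f"EDF file {path.name} is missing montage channel {lab!r}")
        order.append(by_key[key])
    data = raw.get_data()[order] * 1e6  # mne loads volts; keep microvolts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_edf(path: "str | Path", rec: Recording, labels: "tuple[str, ...] | None" = None) -> None:
    """Write a recording as a minimal EDF file (16-bit, 1-s data records).

    Covers what the package needs for fixtures and round-trips: integer
    sampling rates and whole-second durations (trailing samples beyond the
    last full second are dropped, matching EDF's record structure).
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_ch))
    if len(labels) != n_ch:
        raise ValueError("label count mismatch")
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs]

    phys_min = float(np.floor(data.min() - 1.0))
    phys_max = float(np.ceil(data.max() + 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad(f"X X X {rec.subject_id or 'X'}", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, [pad(lab, 16) for lab in labels]),
        (80, [pad("EEG", 80)] * n_ch),
        (8, [pad("uV", 8)] * n_ch),
        (8, [pad(f"{phys_min:.1f}", 8)] * n_ch),
        (8, [pad(f"{phys_max:.1f}", 8)] * n_ch),
        (8, [pad(str(dig_min), 8)] * n_ch),
        (8, [pad(str(dig_max), 8)] * n_ch),
        (80, [pad("", 80)] * n_ch),
        (8, [pad(str(fs), 8)] * n_ch),
        (32, [pad("", 32)] * n_ch),
    ]
    sig_header = b"".join(b"".join(col) for _, col in fields)

    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            f.write(block.tobytes())  # channel-sequential within each record


def sliding_windows(
    rec: Recording, window_s: float = 1.0, overlap: float = 0.5
) -> list[Epoch]:
    """Cut a recording into overlapping fixed-length epochs.

    hop = window * (1 - overlap); the trailing partial window is discarded.
    With the defaults (1 s window, 50% overlap) a 60 s recording at 160 Hz
    yields floor((9600-160)/80)+1 = 119 epochs.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    win = int(round(rec.fs * window_s))
    if win < 1:
        raise ValueError("window shorter than one sample")
    if rec.n_samples < win:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one "
            f"window ({win} samples)"
        )
    hop = max(1, int(round(win * (1.0 - overlap))))
    n_epochs = (rec.n_samples - win) // hop + 1
    return [
        Epoch(
            data=rec.data[:, i * hop : i * hop + win],
            subject_id=rec.subject_id,
            offset=i * hop,
            condition=rec.condition,
        )
        for i in range(n_epochs)
    ]


def bandpass(rec: Recording, low_hz: float, high_hz: float, order: int = 4) -> Recording:
    """Optional zero-phase Butterworth band-pass (off by default everywhere)."""
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = _sig.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return Recording(
        data=_sig.sosfiltfilt(sos, rec.data, axis=1),
        fs=rec.fs,
        subject_id=rec.subject_id,
        condition=rec.condition,
    )
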