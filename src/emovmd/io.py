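"""Recording readers/writers: CSV and 16-bit EDF, with an events sidecar.

CSV layout: one column per channel with a header row of channel names, one
row per sample, full float precision.  EDF follows the European Data Format
spec: an ASCII header plus int16 little-endian data records of one second
each (so the sampling rate must be an integer and the length a whole number
of seconds).  Labels travel in a sidecar ``<stem>_events.csv`` with columns
onset_sample, duration_samples, label; sampling rate and channel names for
CSV recordings live in ``<stem>.meta.json``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .recording import UNKNOWN, Recording, label_segments

__all__ = ["write_recording", "read_recording", "write_events", "read_events"]

_FORMATS = ("csv", "edf")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_events.csv"), Path(f"{stem}.meta.json")


def write_events(labels: np.ndarray, path: Path) -> None:
    rows = [
        {"onset_sample": s, "duration_samples": e - s, "label": lab}
        for s, e, lab in label_segments(labels)
    ]
    pd.DataFrame(rows, columns=["onset_sample", "duration_samples", "label"]).to_csv(
        path, index=False
    )


def read_events(path: Path, n_samples: int) -> np.ndarray:
    table = pd.read_csv(path)
    labels = np.full(n_samples, UNKNOWN, dtype="<U16")
    for _, row in table.iterrows():
        s = int(row["onset_sample"])
        e = s + int(row["duration_samples"])
        if s < 0 or e > n_samples:
            raise ConfigurationError(
                f"event [{s}, {e}) outside the recording of {n_samples} samples"
            )
        labels[s:e] = str(row["label"])
    return labels


def write_recording(recording: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording plus its events sidecar; returns the data path."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ConfigurationError(f"format must be one of {_FORMATS}, got {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    events_path, meta_path = _sidecar_paths(path)
    if fmt == "csv":
        frame = pd.DataFrame(recording.data.T, columns=recording.channel_names)
        frame.to_csv(path, index=False)
        meta_path.write_text(
            json.dumps({"fs": recording.fs, "channels": recording.channel_names})
        )
    else:
        _write_edf(recording, path)
    write_events(recording.labels, events_path)
    return path


def read_recording(
    path: str | Path, format: str | None = None, fs: float | None = None
) -> Recording:
    """Inverse of write_recording (within format precision).

    For CSV the sampling rate comes from the meta sidecar or the ``fs``
    argument; for EDF it comes from the header, and a conflicting ``fs``
    argument is an error.  A missing events sidecar yields an all-unlabeled
    timeline with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ConfigurationError(f"format must be one of {_FORMATS}, got {fmt!r}")
    events_path, meta_path = _sidecar_paths(path)
    if fmt == "csv":
        # round_trip parsing keeps re-read recordings bit-identical
        frame = pd.read_csv(path, float_precision="round_trip")
        data = frame.to_numpy().T
        channels = list(frame.columns)
        file_fs = None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            file_fs = float(meta["fs"])
        if fs is not None and file_fs is not None and abs(fs - file_fs) > 1e-9:
            raise ConfigurationError(
                f"fs mismatch: file says {file_fs} Hz, caller says {fs} Hz"
            )
        final_fs = fs if fs is not None else file_fs
        if final_fs is None:
            raise ConfigurationError(
                "sampling rate unknown: no meta sidecar and no fs argument"
            )
    else:
        data, channels, final_fs = _read_edf(path)
        if fs is not None and abs(fs - final_fs) > 1e-9:
            raise ConfigurationError(
                f"fs mismatch: EDF header says {final_fs} Hz, caller says {fs} Hz"
            )
    if events_path.exists():
        labels = read_events(events_path, data.shape[1])
    else:
        warnings.warn(
            f"no events sidecar at {events_path}; timeline left unlabeled", stacklevel=2
        )
        labels = np.full(data.shape[1], UNKNOWN, dtype="<U16")
    return Recording(data=data, fs=final_fs, channel_names=channels, labels=labels)


def _ascii(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        raise ConfigurationError(f"EDF field {text!r} exceeds {width} ascii chars")
    return text.ljust(width).encode("ascii")


def _write_edf(recording: Recording, path: Path) -> None:
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_ch = recording.n_channels
    if recording.n_samples % fs_i != 0:
        raise ConfigurationError(
            "EDF writer requires a whole number of 1 s data records "
            f"({recording.n_samples} samples at {fs_i} Hz)"
        )
    n_records = recording.n_samples // fs_i

    phys_max = np.maximum(np.abs(recording.data).max(axis=1), 1e-3)
    phys_max = np.array([float(f"{p * 1.01:.6g}") for p in phys_max])  # headroom, 8-char safe
    dig_max, dig_min = 32767, -32768
    scale = (2 * phys_max) / (dig_max - dig_min)

    header = b""
    header += _ascii("0", 8)  # version
    header += _ascii("X", 80)  # patient id
    header += _ascii("synthetic emovmd session", 80)
    header += _ascii("01.01.00", 8)  # fixed date/time keep output deterministic
    header += _ascii("00.00.00", 8)
    header += _ascii(256 + 256 * n_ch, 8)  # header length
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)  # record duration, seconds
    header += _ascii(n_ch, 4)
    for name in recording.channel_names:
        header += _ascii(name, 16)
    header += b"".join(_ascii("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch))
    header += b"".join(_ascii(f"{-p:.6g}"[:8], 8) for p in phys_max)
    header += b"".join(_ascii(f"{p:.6g}"[:8], 8) for p in phys_max)
    header += b"".join(_ascii(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_ascii(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))  # prefilter
    header += b"".join(_ascii(fs_i, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 32) for _ in range(n_ch))

    digital = np.empty((n_ch, recording.n_samples), dtype="<i2")
    for c in range(n_ch):
        digital[c] = np.clip(
            np.round(recording.data[c] / scale[c]), dig_min, dig_max
        ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs_i : (r + 1) * fs_i]
            fh.write(block.tobytes())  # channel-major within each record


def _read_edf(path: Path) -> tuple[np.ndarray, list[str], float]:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ConfigurationError(f"truncated EDF header in {path} (byte {len(raw)})")

    def field(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    header_len = int(field(184, 8))
    n_records = int(field(236, 8))
    record_dur = float(field(244, 8))
    n_ch = int(field(252, 4))
    if len(raw) < header_len:
        raise ConfigurationError(f"truncated EDF header in {path} (byte {len(raw)})")

    off = 256
    labels = [field(off + 16 * i, 16) for i in range(n_ch)]
    off += 16 * n_ch + 80 * n_ch + 8 * n_ch  # skip transducer, phys dim
    phys_min = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    phys_max = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dig_min = np.array([int(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dig_max = np.array([int(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch + 80 * n_ch
    spr = np.array([int(field(off + 8 * i, 8)) for i in range(n_ch)])

    if len(set(spr.tolist())) != 1:
        raise ConfigurationError("mixed per-channel sampling rates are not supported")
    fs = spr[0] / record_dur
    expected = header_len + 2 * n_records * int(spr.sum())
    if len(raw) < expected:
        raise ConfigurationError(
            f"truncated EDF data in {path}: {len(raw)} bytes, expected {expected} "
            f"(failure at byte {len(raw)})"
        )
    body = np.frombuffer(raw, dtype="<i2", offset=header_len, count=n_records * int(spr.sum()))
    body = body.reshape(n_records, n_ch, spr[0])
    digital = body.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return data, labels, float(fs)
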