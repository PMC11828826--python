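"""Sliding-window band-power features of VMD modes.

Each emotion-labeled window is decomposed per channel into K modes; the
power of every mode in each canonical band forms a K x 5 feature block,
aggregated across channels (mean by default) into one row of the feature
matrix.  Band power uses the normalization

    P = (1/N^2) * sum_{bins in band, with mirror bins} |X[m]|^2,

so the powers of all bands tile the window's mean squared amplitude exactly
(Parseval) and are invariant to window length for stationary content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import Band, DEFAULT_BANDS
from .errors import ConfigurationError, NoLabeledWindowsError
from .recording import RELAX, UNKNOWN, Recording, label_segments
from .vmd import VMDConfig, _vmd_batch

__all__ = [
    "WindowSpec",
    "slide_windows",
    "band_power",
    "band_power_matrix",
    "feature_columns",
    "extract_features",
]

_MODE_ORDERS = ("ascending", "descending")


@dataclass
class WindowSpec:
    """Sliding-window geometry: length in seconds and fractional overlap."""

    length_s: float = 3.0
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ConfigurationError("window length must be positive")
        if not (0 <= self.overlap_frac < 1):
            raise ConfigurationError("overlap_frac must lie in [0, 1)")

    def length_samples(self, fs: float) -> int:
        return int(round(self.length_s * fs))

    def hop_samples(self, fs: float) -> int:
        return max(1, int(round(self.length_samples(fs) * (1 - self.overlap_frac))))


def slide_windows(n_samples: int, fs: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open (start, end) sample spans starting at 0.

    Hop = window x (1 - overlap); a trailing partial window is discarded.
    """
    win = spec.length_samples(fs)
    if win > n_samples:
        raise ConfigurationError(
            f"window of {win} samples longer than signal of {n_samples}"
        )
    hop = spec.hop_samples(fs)
    count = (n_samples - win) // hop + 1
    return [(i * hop, i * hop + win) for i in range(count)]


def _mirror_weights(n: int) -> np.ndarray:
    """Per-rfft-bin multiplicity: 2 for bins with a negative-frequency twin."""
    n_bins = n // 2 + 1
    w = np.full(n_bins, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0  # Nyquist bin has no twin
    return w


def _band_bin_mask(freqs: np.ndarray, band: Band) -> np.ndarray:
    if band.closed_upper:
        return (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    return (freqs >= band.lo_hz) & (freqs < band.hi_hz)


def band_power(mode: np.ndarray, fs: float, band: Band) -> float:
    """Mean-square power of a window restricted to one frequency band."""
    mode = np.asarray(mode, dtype=float)
    if mode.ndim != 1:
        raise ConfigurationError("band_power expects a 1-D window")
    if not np.all(np.isfinite(mode)):
        raise ConfigurationError("window contains non-finite samples")
    if band.lo_hz < 0 or band.hi_hz > fs / 2:
        raise ConfigurationError(
            f"band [{band.lo_hz}, {band.hi_hz}] outside the Nyquist range [0, {fs / 2}]"
        )
    n = mode.size
    spectrum = np.abs(np.fft.rfft(mode)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = _band_bin_mask(freqs, band)
    return float((spectrum[mask] * _mirror_weights(n)[mask]).sum() / n**2)


def band_power_matrix(
    modes: np.ndarray, fs: float, bands: tuple[Band, ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Band powers of a stack of windows: (..., N) -> (..., len(bands))."""
    modes = np.asarray(modes, dtype=float)
    n = modes.shape[-1]
    spectrum = np.abs(np.fft.rfft(modes, axis=-1)) ** 2 * _mirror_weights(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    out = np.empty(modes.shape[:-1] + (len(bands),))
    for j, band in enumerate(bands):
        if band.lo_hz < 0 or band.hi_hz > fs / 2:
            raise ConfigurationError(f"band {band.name} outside Nyquist range")
        mask = _band_bin_mask(freqs, band)
        out[..., j] = spectrum[..., mask].sum(axis=-1) / n**2
    return out


def feature_columns(
    n_modes: int = 5, bands: tuple[Band, ...] = DEFAULT_BANDS
) -> list[str]:
    """Canonical feature-column names, mode-major: IMF1_Delta ... IMF5_Gamma."""
    return [f"IMF{k + 1}_{band.name}" for k in range(n_modes) for band in bands]


def extract_features(
    recording: Recording,
    window: WindowSpec | None = None,
    vmd: VMDConfig | None = None,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    channel_policy: str = "mean",
    mode_order: str = "ascending",
) -> pd.DataFrame:
    """Feature matrix over all single-emotion windows of a recording.

    Windows that straddle a label boundary or contain relax/unlabeled
    samples are dropped.  ``channel_policy`` is ``"mean"`` (average band
    powers over channels, the default 25-feature layout), ``"per_channel"``
    (one row per window per channel, with a ``channel`` column) or a channel
    name.  ``mode_order`` maps decomposition modes to IMF column indices:
    ``"ascending"`` puts the lowest center frequency in IMF1,
    ``"descending"`` in IMF{K}.
    """
    if window is None:
        window = WindowSpec()
    if vmd is None:
        vmd = VMDConfig()
    if mode_order not in _MODE_ORDERS:
        raise ConfigurationError(f"mode_order must be one of {_MODE_ORDERS}")
    if channel_policy not in ("mean", "per_channel"):
        ch_idx = [recording.channel_index(channel_policy)]
    else:
        ch_idx = list(range(recording.n_channels))

    spans = slide_windows(recording.n_samples, recording.fs, window)
    labels = recording.labels

    # map samples to contiguous-segment ids for trial-aware splitting
    seg_id = np.empty(recording.n_samples, dtype=int)
    for i, (s, e, _lab) in enumerate(label_segments(labels)):
        seg_id[s:e] = i

    keep: list[tuple[int, int, str, int]] = []
    for s, e in spans:
        window_labels = labels[s:e]
        lab = str(window_labels[0])
        if lab in (RELAX, UNKNOWN) or np.any(window_labels != lab):
            continue
        keep.append((s, e, lab, int(seg_id[s])))
    if not keep:
        raise NoLabeledWindowsError(
            f"no window of {window.length_s}s carries a single emotion label "
            f"({len(spans)} windows scanned; labels present: "
            f"{sorted(set(map(str, labels)))})"
        )

    columns = feature_columns(vmd.K, bands)
    rows = []
    meta = []
    data = recording.data[ch_idx]
    for s, e, lab, seg in keep:
        results_modes, _freqs, _it, _res = _vmd_batch(data[:, s:e], recording.fs, vmd)
        # _vmd_batch sorts modes ascending by center frequency
        if mode_order == "descending":
            results_modes = results_modes[:, ::-1, :]
        powers = band_power_matrix(results_modes, recording.fs, bands)  # (C, K, B)
        if channel_policy == "per_channel":
            for c, ch in enumerate(ch_idx):
                rows.append(powers[c].reshape(-1))
                meta.append((s, lab, seg, recording.channel_names[ch]))
        else:
            rows.append(powers.mean(axis=0).reshape(-1))
            meta.append((s, lab, seg, channel_policy))

    df = pd.DataFrame(np.asarray(rows), columns=columns)
    df["window_start_sample"] = [m[0] for m in meta]
    df["window_start_s"] = df["window_start_sample"] / recording.fs
    df["label"] = [m[1] for m in meta]
    df["segment_id"] = [m[2] for m in meta]
    df["channel_policy"] = [m[3] for m in meta]
    return df
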