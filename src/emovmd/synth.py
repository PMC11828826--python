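"""Synthetic EEG generator emulating a visual emotion-elicitation paradigm.

A session alternates relaxation periods with blocks of emotion-inducing
images (happy, sad, fear).  Each emotion condition contributes band-limited
AM-FM oscillations u(t) = A(t) cos(φ(t)) on top of 1/f background noise,
slow polynomial drift and stereotyped frontal blink artifacts, so that every
downstream stage (filtering, detrending, ICA, VMD, band-power features,
classification) has a known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bands import Band, band_lookup
from .errors import ConfigurationError
from .recording import RELAX, Recording

__all__ = [
    "CHANNELS_32",
    "ParadigmSpec",
    "ComponentSpec",
    "DriftSpec",
    "BlinkSpec",
    "ClassEffectSpec",
    "GroundTruth",
    "build_timeline",
    "generate_am_fm",
    "generate_recording",
    "default_effects",
    "null_effects",
]

#: 10-20 montage of the 32-channel gel headset emulated by the generator.
CHANNELS_32 = [
    "Fp1", "F7", "F3", "FC1", "Cz", "Fz", "C3", "FC5",
    "FT9", "T7", "CP5", "CP1", "P3", "P7", "PO9", "O1",
    "Oz", "Pz", "O2", "PO10", "P4", "P8", "CP2", "CP6",
    "T8", "FT10", "FC6", "C4", "Fp2", "F4", "F8", "FC2",
]


@dataclass
class ParadigmSpec:
    """Timing of the stimulus paradigm: per phase, an initial relax period
    followed by image blocks for each emotion, with relax intervals between
    emotions.  Defaults mirror a 10 s relax / three 5 s images per emotion /
    5 s inter-emotion relax / two-phase session at 128 Hz on 32 channels."""

    fs: float = 128.0
    n_channels: int = 32
    channel_names: Sequence[str] | None = None
    relax_initial_s: float = 10.0
    image_duration_s: float = 5.0
    images_per_emotion: int = 3
    inter_emotion_relax_s: float = 5.0
    emotion_order: tuple[str, ...] = ("happy", "sad", "fear")
    n_phases: int = 2

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("need at least one channel")
        for name, v in [
            ("relax_initial_s", self.relax_initial_s),
            ("image_duration_s", self.image_duration_s),
            ("inter_emotion_relax_s", self.inter_emotion_relax_s),
        ]:
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.images_per_emotion < 1 or self.n_phases < 1:
            raise ConfigurationError("images_per_emotion and n_phases must be >= 1")
        if not self.emotion_order:
            raise ConfigurationError("emotion_order must be non-empty")
        if len(set(self.emotion_order)) != len(self.emotion_order):
            raise ConfigurationError("emotion_order entries must be unique")
        if RELAX in self.emotion_order:
            raise ConfigurationError(f"{RELAX!r} is reserved for rest periods")
        if self.channel_names is None:
            if self.n_channels <= len(CHANNELS_32):
                # keep the frontal-polar pair in every reduced montage so the
                # blink model and ICA reference stay meaningful
                ordered = ["Fp1", "Fp2"] + [
                    c for c in CHANNELS_32 if c not in ("Fp1", "Fp2")
                ]
                self.channel_names = ordered[: self.n_channels]
            else:
                raise ConfigurationError(
                    "channel_names required when n_channels exceeds the built-in montage"
                )
        else:
            self.channel_names = list(self.channel_names)
            if len(self.channel_names) != self.n_channels:
                raise ConfigurationError("channel_names length must equal n_channels")

    @property
    def emotion_block_s(self) -> float:
        return self.images_per_emotion * self.image_duration_s

    @property
    def phase_duration_s(self) -> float:
        k = len(self.emotion_order)
        return (
            self.relax_initial_s
            + k * self.emotion_block_s
            + (k - 1) * self.inter_emotion_relax_s
        )

    @property
    def total_duration_s(self) -> float:
        return self.n_phases * self.phase_duration_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.fs))


@dataclass
class ComponentSpec:
    """One AM-FM oscillation injected during a class's segments.

    The carrier must lie inside the named band; the amplitude envelope is
    ``amplitude * (1 + am_depth * sin(2π am_freq_hz t))`` (non-negative for
    am_depth <= 1).
    """

    band: str
    carrier_hz: float
    amplitude: float
    am_depth: float = 0.0
    am_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        band = band_lookup(self.band)
        if not band.contains(self.carrier_hz):
            raise ConfigurationError(
                f"carrier {self.carrier_hz} Hz outside band {self.band} "
                f"[{band.lo_hz}, {band.hi_hz})"
            )
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")
        if not (0 <= self.am_depth <= 1):
            raise ConfigurationError("am_depth must lie in [0, 1]")


@dataclass
class DriftSpec:
    """Slow per-channel polynomial baseline drift."""

    degree: int = 2
    amplitude: float = 20.0

    def __post_init__(self) -> None:
        if self.degree < 0 or self.amplitude < 0:
            raise ConfigurationError("drift degree and amplitude must be non-negative")


@dataclass
class BlinkSpec:
    """Stereotyped ocular blink bursts on the frontal-polar channels.

    Each blink is a squared-cosine (Hann) bump added at unit gain on the
    listed channels and at ``leakage`` gain on every other channel whose
    10-20 name starts with 'F' or 'AF' (frontal leakage), giving ICA a
    spatially fixed, recoverable source.
    """

    rate_per_min: float = 10.0
    amplitude: float = 75.0
    duration_s: float = 0.4
    channels: tuple[str, ...] = ("Fp1", "Fp2")
    leakage: float = 0.3

    def __post_init__(self) -> None:
        if self.rate_per_min < 0 or self.amplitude < 0:
            raise ConfigurationError("blink rate and amplitude must be non-negative")
        if self.duration_s <= 0:
            raise ConfigurationError("blink duration must be positive")


@dataclass
class ClassEffectSpec:
    """Everything the generator injects: per-class band components plus the
    class-independent noise, drift and artifact processes."""

    components: Mapping[str, Mapping[str, ComponentSpec]] = field(default_factory=dict)
    noise_pink_scale: float = 2.0
    n_shared_noise_sources: int = 4
    shared_noise_scale: float = 0.6
    drift: DriftSpec = field(default_factory=DriftSpec)
    blink: BlinkSpec = field(default_factory=BlinkSpec)

    def __post_init__(self) -> None:
        if self.noise_pink_scale < 0 or self.shared_noise_scale < 0:
            raise ConfigurationError("noise scales must be non-negative")
        for cls, bandmap in self.components.items():
            for band_name, comp in bandmap.items():
                if comp.band != band_name:
                    raise ConfigurationError(
                        f"component under key {band_name!r} declares band {comp.band!r}"
                    )

    def validate_against(self, spec: ParadigmSpec) -> None:
        shortest = min(
            spec.relax_initial_s, spec.inter_emotion_relax_s, spec.emotion_block_s
        )
        if self.blink.rate_per_min > 0 and self.blink.duration_s >= shortest:
            raise ConfigurationError(
                f"blink duration {self.blink.duration_s}s must be shorter than the "
                f"shortest paradigm segment ({shortest}s)"
            )
        for cls in self.components:
            if cls not in spec.emotion_order:
                raise ConfigurationError(f"components given for unknown class {cls!r}")


@dataclass
class GroundTruth:
    """Everything a downstream recovery test needs to know about a session."""

    carrier_hz: dict[str, dict[str, float]]
    clean: np.ndarray  # components + noise, before drift and artifacts
    blink_onsets: np.ndarray  # sample indices
    drift_coeffs: np.ndarray  # (channels, degree + 1), numpy polyval order
    discriminative_band: str | None
    discriminative_rank: int | None  # ascending-frequency rank among carriers
    component_gains: dict[str, dict[str, np.ndarray]] | None = None  # topographies

    def discriminative_column(self, n_modes: int = 5, mode_order: str = "ascending") -> str:
        """Feature-column name of the planted effect under a mode ordering."""
        if self.discriminative_band is None or self.discriminative_rank is None:
            raise ConfigurationError("this ground truth has no discriminative effect")
        if mode_order == "ascending":
            k = self.discriminative_rank + 1
        elif mode_order == "descending":
            k = n_modes - self.discriminative_rank
        else:
            raise ConfigurationError(f"unknown mode_order {mode_order!r}")
        return f"IMF{k}_{self.discriminative_band}"


def default_effects() -> ClassEffectSpec:
    """The study-default class structure.

    Every class carries identical Theta/Alpha/Beta/Gamma oscillations (so all
    five decomposition modes are occupied); the discriminative signal is a
    2 Hz Delta component whose amplitude differs by class (fear 2,
    happy 3.5, sad 5), i.e. the informative feature is the Delta power of
    the lowest-frequency mode.  Every class keeps a 2 Hz carrier strong
    enough to anchor the lowest mode's center frequency in all conditions;
    otherwise that frequency would relocate per class and spread class
    information across every band of every mode through the renormalized
    Wiener-filter weights.
    """
    shared = {
        "Theta": ComponentSpec("Theta", 6.0, 1.5, am_depth=0.2),
        "Alpha": ComponentSpec("Alpha", 10.0, 1.5, am_depth=0.2),
        "Beta": ComponentSpec("Beta", 21.0, 1.2, am_depth=0.2),
        "Gamma": ComponentSpec("Gamma", 35.0, 0.8, am_depth=0.2),
    }
    comps = {
        "happy": {"Delta": ComponentSpec("Delta", 2.0, 3.5, am_depth=0.2), **shared},
        "sad": {"Delta": ComponentSpec("Delta", 2.0, 5.0, am_depth=0.2), **shared},
        "fear": {"Delta": ComponentSpec("Delta", 2.0, 2.0, am_depth=0.2), **shared},
    }
    return ClassEffectSpec(components=comps)


def null_effects(pink_scale: float = 2.0) -> ClassEffectSpec:
    """Pink noise only: no class structure, no drift, no blinks.

    Used for chance-level soundness checks.
    """
    return ClassEffectSpec(
        components={},
        noise_pink_scale=pink_scale,
        drift=DriftSpec(degree=0, amplitude=0.0),
        blink=BlinkSpec(rate_per_min=0.0),
    )


def build_timeline(spec: ParadigmSpec) -> np.ndarray:
    """Per-sample label array for the paradigm.

    Each phase is relax(initial) followed by, for each emotion in order, an
    image block (images_per_emotion x image_duration) and an inter-emotion
    relax interval (omitted after the last emotion).  Segment boundaries are
    half-open [start, end) in samples, with the time origin at sample 0.
    """
    fs = spec.fs
    pieces: list[tuple[str, float]] = []
    for _ in range(spec.n_phases):
        pieces.append((RELAX, spec.relax_initial_s))
        for i, emotion in enumerate(spec.emotion_order):
            pieces.append((emotion, spec.emotion_block_s))
            if i < len(spec.emotion_order) - 1:
                pieces.append((RELAX, spec.inter_emotion_relax_s))
    labels = np.empty(spec.n_samples, dtype="<U16")
    cursor = 0.0
    start = 0
    for label, dur in pieces:
        cursor += dur
        end = int(round(cursor * fs))
        labels[start:end] = label
        start = end
    labels[start:] = RELAX  # rounding slack, if any
    return labels


def generate_am_fm(
    amplitude_fn: Callable[[np.ndarray], np.ndarray],
    phase_fn: Callable[[np.ndarray], np.ndarray],
    fs: float,
    n_samples: int,
) -> np.ndarray:
    """Sample an AM-FM mode u(t) = A(t) cos(φ(t)) at rate fs.

    The amplitude envelope must be non-negative everywhere; the phase should
    be nondecreasing (an incremental function) for a physically meaningful
    instantaneous frequency, though only the amplitude sign is enforced.
    """
    if fs <= 0 or n_samples < 0:
        raise ConfigurationError("fs must be positive and n_samples non-negative")
    t = np.arange(n_samples) / fs
    amp = np.asarray(amplitude_fn(t), dtype=float)
    amp = np.broadcast_to(amp, t.shape)
    if np.any(amp < 0):
        raise ConfigurationError("amplitude envelope must be non-negative")
    phase = np.asarray(phase_fn(t), dtype=float)
    return amp * np.cos(phase)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f (power) noise via spectral shaping of white noise."""
    n_bins = n // 2 + 1
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros(n_bins)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)) * shaping
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_pulse(n: int) -> np.ndarray:
    """Smooth unimodal squared-cosine bump of length n, peak 1."""
    tau = np.linspace(0.0, 1.0, n)
    return np.sin(np.pi * tau) ** 2


def generate_recording(
    spec: ParadigmSpec,
    effects: ClassEffectSpec | None = None,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Simulate one labeled session.

    Per channel: the class-dependent AM-FM components gated to that class's
    segments, plus per-channel pink noise and a low-rank shared pink
    background (so ICA has a meaningful mixing structure), plus polynomial
    drift and frontal blink bursts.  Identical seeds give bit-identical
    output.  GroundTruth stores the pre-drift, pre-artifact data and every
    injected parameter.
    """
    if effects is None:
        effects = default_effects()
    effects.validate_against(spec)
    rng = np.random.default_rng(seed)

    fs = spec.fs
    n = spec.n_samples
    n_ch = spec.n_channels
    t = np.arange(n) / fs
    labels = build_timeline(spec)

    # class-dependent oscillations.  Two realism details that matter for the
    # downstream contracts: (a) the AM envelope phase is drawn fresh for
    # every segment occurrence — a global envelope would be phase-locked to
    # the periodic paradigm and leak class identity into every band through
    # the stimulus schedule; (b) each component has a fixed signed
    # per-channel topography (dipolar sources project with either polarity),
    # normalized to unit mean square so channel-averaged band powers scale
    # exactly with amplitude^2.  A uniform same-sign topography would make
    # the component mimic an ocular source for the frontal-correlation
    # criterion.
    from .recording import label_segments

    segments = label_segments(labels)
    clean = np.zeros((n_ch, n))
    carrier_hz: dict[str, dict[str, float]] = {}
    component_gains: dict[str, dict[str, np.ndarray]] = {}
    for cls in spec.emotion_order:
        bandmap = effects.components.get(cls)
        if not bandmap:
            continue
        carrier_hz[cls] = {}
        component_gains[cls] = {}
        for band_name in sorted(bandmap):
            comp = bandmap[band_name]
            carrier_hz[cls][band_name] = comp.carrier_hz
            gains = rng.standard_normal(n_ch)
            gains /= np.sqrt(np.mean(gains**2))
            component_gains[cls][band_name] = gains
            wave = np.zeros(n)
            for s, e, lab in segments:
                if lab != cls:
                    continue
                tt = t[s:e]
                am_phase = rng.uniform(0.0, 2 * np.pi)
                env = comp.amplitude * (
                    1.0
                    + comp.am_depth * np.sin(2 * np.pi * comp.am_freq_hz * tt + am_phase)
                )
                wave[s:e] = env * np.cos(2 * np.pi * comp.carrier_hz * tt)
            clean += np.outer(gains, wave)

    # background noise: independent pink per channel + shared low-rank pink
    for ch in range(n_ch):
        clean[ch] += effects.noise_pink_scale * _pink_noise(rng, n)
    if effects.n_shared_noise_sources > 0 and effects.shared_noise_scale > 0:
        sources = np.stack(
            [_pink_noise(rng, n) for _ in range(effects.n_shared_noise_sources)]
        )
        mixing = rng.standard_normal((n_ch, effects.n_shared_noise_sources))
        clean += effects.shared_noise_scale * mixing @ sources

    data = clean.copy()

    # slow polynomial drift per channel
    deg = effects.drift.degree
    drift_coeffs = np.zeros((n_ch, deg + 1))
    if effects.drift.amplitude > 0:
        tn = np.linspace(-1.0, 1.0, n)
        for ch in range(n_ch):
            coeffs = rng.uniform(-1.0, 1.0, deg + 1)
            trend = np.polyval(coeffs, tn)
            peak = np.max(np.abs(trend))
            scale = effects.drift.amplitude / peak if peak > 0 else 0.0
            drift_coeffs[ch] = coeffs * scale
            data[ch] += trend * scale

    # frontal blink artifacts
    blink = effects.blink
    blink_len = int(round(blink.duration_s * fs))
    n_blinks = int(round(blink.rate_per_min * spec.total_duration_s / 60.0))
    onsets = np.array([], dtype=int)
    if blink.amplitude > 0 and n_blinks > 0 and blink_len > 1:
        onsets = np.sort(rng.integers(0, n - blink_len, size=n_blinks))
        gains = np.zeros(n_ch)
        for ch_name in blink.channels:
            if ch_name in spec.channel_names:
                gains[spec.channel_names.index(ch_name)] = 1.0
        for i, ch_name in enumerate(spec.channel_names):
            if gains[i] == 0.0 and ch_name.upper().startswith(("F", "AF")):
                gains[i] = blink.leakage
        pulse = blink.amplitude * _blink_pulse(blink_len)
        for onset in onsets:
            data[:, onset : onset + blink_len] += np.outer(gains, pulse)

    # planted discriminative feature: the band whose amplitudes differ by class
    disc_band: str | None = None
    disc_rank: int | None = None
    all_bands: set[str] = set()
    for bandmap in effects.components.values():
        all_bands.update(bandmap.keys())
    band_amps: dict[str, set[float]] = {b: set() for b in all_bands}
    for cls in spec.emotion_order:
        bandmap = effects.components.get(cls, {})
        for band_name in all_bands:
            amp = bandmap[band_name].amplitude if band_name in bandmap else 0.0
            band_amps[band_name].add(amp)
    varying = [b for b, amps in band_amps.items() if len(amps) > 1]
    if len(varying) == 1:
        disc_band = varying[0]
        all_freqs = sorted(
            {c.carrier_hz for m in effects.components.values() for c in m.values()}
        )
        disc_freq = min(
            c.carrier_hz
            for m in effects.components.values()
            for c in m.values()
            if c.band == disc_band
        )
        disc_rank = all_freqs.index(disc_freq)

    recording = Recording(
        data=data, fs=fs, channel_names=list(spec.channel_names), labels=labels
    )
    truth = GroundTruth(
        carrier_hz=carrier_hz,
        clean=clean,
        blink_onsets=onsets,
        drift_coeffs=drift_coeffs,
        discriminative_band=disc_band,
        discriminative_rank=disc_rank,
        component_gains=component_gains,
    )
    return recording, truth
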