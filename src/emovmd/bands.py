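"""Canonical EEG frequency bands.

Band edges follow the clinical convention used throughout the pipeline:
Delta [0.5, 4), Theta [4, 8), Alpha [8, 12), Beta [12, 30), Gamma [30, 45].
Intervals are half-open on the upper edge except Gamma, whose upper edge is
closed at the 45 Hz bandpass cutoff (nothing above it survives preprocessing).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class Band:
    """A named frequency interval [lo_hz, hi_hz), optionally closed above."""

    name: str
    lo_hz: float
    hi_hz: float
    closed_upper: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 <= lo < hi, got [{self.lo_hz}, {self.hi_hz})"
            )

    def contains(self, freq_hz: float) -> bool:
        if self.closed_upper:
            return self.lo_hz <= freq_hz <= self.hi_hz
        return self.lo_hz <= freq_hz < self.hi_hz


DELTA = Band("Delta", 0.5, 4.0)
THETA = Band("Theta", 4.0, 8.0)
ALPHA = Band("Alpha", 8.0, 12.0)
BETA = Band("Beta", 12.0, 30.0)
GAMMA = Band("Gamma", 30.0, 45.0, closed_upper=True)

DEFAULT_BANDS: tuple[Band, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def band_lookup(name: str) -> Band:
    try:
        return BAND_BY_NAME[name]
    except KeyError:
        raise ConfigurationError(f"unknown band name {name!r}") from None
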