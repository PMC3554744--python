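"""Frequency-band definitions for BOLD low-frequency oscillation analysis.

The canonical oscillation taxonomy splits the classic resting-state range
into slow-5 (0.01-0.027 Hz) and slow-4 (0.027-0.073 Hz); their union
(0.01-0.073 Hz) is the whole analysis band. All three ship as defaults and
arbitrary user bands are supported, subject to the Nyquist limit 1/(2*TR).
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidDesignError(ValueError):
    """A band, coupling, or cohort design parameter is out of range."""


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval [low, high] in Hz.

    Band edges are inclusive on both sides when mapped onto discrete
    Fourier bins, so slow-5 and slow-4 share the 0.027 Hz edge bin.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high):
            raise InvalidDesignError(
                f"band {self.name!r}: need 0 <= low < high, got [{self.low}, {self.high}]"
            )

    def validate_nyquist(self, tr_seconds: float) -> None:
        """Raise if the band exceeds the Nyquist frequency for this TR."""
        nyq = 0.5 / tr_seconds
        if self.high > nyq + 1e-12:
            raise InvalidDesignError(
                f"band {self.name!r} upper edge {self.high} Hz exceeds "
                f"Nyquist {nyq} Hz at TR={tr_seconds}s"
            )
        if self.low >= nyq:
            raise InvalidDesignError(
                f"band {self.name!r} lies entirely above Nyquist {nyq} Hz"
            )


SLOW5 = BandSpec("slow5", 0.01, 0.027)
SLOW4 = BandSpec("slow4", 0.027, 0.073)
WHOLEBAND = BandSpec("wholeband", 0.01, 0.073)

DEFAULT_BANDS: tuple[BandSpec, ...] = (SLOW5, SLOW4, WHOLEBAND)


def band_by_name(name: str) -> BandSpec:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; defaults are "
                   f"{[b.name for b in DEFAULT_BANDS]}")
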