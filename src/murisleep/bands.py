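"""Spectral band definitions.

Band edges are half-open intervals (lo, hi], so the gaps between delta and
theta (4-5.1 Hz) and between theta and alpha (9-9.1 Hz) belong to no named
band, and the named bands never overlap. The "total" band (0.1-30 Hz) spans
all named bands plus the gaps, so the sum of named band powers is always
bounded by total power.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, half-open (lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need 0 <= lo < hi, got ({self.lo}, {self.hi})")

    def contains(self, f: float) -> bool:
        return self.lo < f <= self.hi


DELTA = BandDefinition("delta", 0.1, 4.0)
THETA = BandDefinition("theta", 5.1, 9.0)
ALPHA = BandDefinition("alpha", 9.1, 12.0)
BETA = BandDefinition("beta", 12.0, 20.0)
TOTAL = BandDefinition("total", 0.1, 30.0)

#: The four named analysis bands (excluding "total").
DEFAULT_BANDS = (DELTA, THETA, ALPHA, BETA)
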