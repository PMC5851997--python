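"""Min/mean/max uncertainty triples.

Emission-factor uncertainty is carried as an explicit (min, mean, max)
range rather than a confidence interval: the three layers propagate
through every arithmetic step by interval arithmetic (min combines with
min, max with max).
"""
from __future__ import annotations

from typing import NamedTuple


class Range(NamedTuple):
    """An uncertainty triple. Invariant: min <= mean <= max."""

    min: float
    mean: float
    max: float

    def validate(self) -> "Range":
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"range not ordered: {self}")
        return self

    def __add__(self, other):  # type: ignore[override]
        if isinstance(other, Range):
            return Range(self.min + other.min, self.mean + other.mean, self.max + other.max)
        return Range(self.min + other, self.mean + other, self.max + other)

    __radd__ = __add__

    def scale(self, factor: float) -> "Range":
        """Multiply all three layers by a nonnegative scalar."""
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return Range(self.min * factor, self.mean * factor, self.max * factor)


ZERO = Range(0.0, 0.0, 0.0)


def envelope(ranges: list[Range]) -> Range:
    """Combine member ranges: unweighted mean of means, widest min/max.

    The envelope keeps the conservative explicit-extremes treatment of
    uncertainty: the combined range contains every member's range.
    """
    if not ranges:
        raise ValueError("need at least one range")
    return Range(
        min(r.min for r in ranges),
        sum(r.mean for r in ranges) / len(ranges),
        max(r.max for r in ranges),
    )
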