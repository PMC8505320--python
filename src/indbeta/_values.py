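"""Tagged ratio values for dissimilarity indices.

Every index in this package is a ratio of non-negative integers. When the
denominator is zero (e.g. comparing two empty censuses, or asking for the
compositional-shift fraction of a community with no individual turnover) the
index is mathematically undefined. Batch runs over many plots must not crash
on such plots, and silently coercing to 0 would bias plot-level summaries, so
undefined values propagate as tagged markers carrying the reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction


@dataclass(frozen=True)
class IndexValue:
    """A dissimilarity-index value: an exact rational, or undefined.

    Attributes
    ----------
    fraction : Fraction or None
        Exact value as a ratio of integers, ``None`` when undefined.
    reason : str or None
        Why the value is undefined (``None`` when defined).
    """

    fraction: Fraction | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.fraction is not None

    @property
    def value(self) -> float:
        """Float value; NaN when undefined."""
        return float(self.fraction) if self.fraction is not None else math.nan

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.fraction is None:
            return f"IndexValue(undefined: {self.reason})"
        return f"IndexValue({self.fraction} = {float(self.fraction):.6g})"


def ratio(numerator: int, denominator: int, zero_reason: str) -> IndexValue:
    """Exact integer ratio, tagged undefined when the denominator is zero."""
    if denominator == 0:
        return IndexValue(None, zero_reason)
    return IndexValue(Fraction(int(numerator), int(denominator)))
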