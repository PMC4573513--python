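"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Display tables round half-up (so 19.15 -> 19.2), matching how published
    epidemiologic tables are conventionally typeset, rather than banker's
    rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentages(counts: Sequence[float], decimals: int = 1) -> list[float]:
    """Row percentages of ``counts`` over their own sum, rounded half-up.

    The denominator is the sum of the supplied (non-missing) counts only.
    Returns an empty list when the total is zero.
    """
    total = float(np.sum(counts))
    if total == 0:
        return []
    return [round_half_up(100.0 * c / total, decimals) for c in counts]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
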