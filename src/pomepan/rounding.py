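"""Half-away-from-zero rounding helpers for reported summaries.

Python's built-in ``round`` is banker's rounding; published tables in this
domain round halves away from zero, so summary percentages and means go
through these helpers instead.
"""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    scale = 10.0**ndigits
    scaled = x * scale
    # nudge by an epsilon proportional to magnitude to absorb float noise
    # (e.g. 2.675*100 stored as 267.49999...)
    eps = 1e-9 * max(1.0, abs(scaled))
    rounded = math.floor(abs(scaled) + 0.5 + eps) * math.copysign(1.0, scaled)
    return rounded / scale


def percent(count: float, total: float) -> float:
    """Percentage of ``count`` in ``total``, one decimal; two when below 1%.

    Values under one percent are conventionally printed with two decimals
    (0.64, 0.49); everything else with one (81.3, 98.9).
    """
    if total == 0:
        raise ZeroDivisionError("percent of an empty total")
    raw = 100.0 * count / total
    if abs(raw) < 1.0:
        return round_half_away(raw, 2)
    return round_half_away(raw, 1)


def mean_rounded(total: float, n: int) -> int:
    """Integer mean total/n, half away from zero; 0 when n == 0."""
    if n == 0:
        return 0
    return int(round_half_away(total / n, 0))
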