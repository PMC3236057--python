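"""Small shared helpers."""

from __future__ import annotations

import math

#: Average month length used to convert week-denominated rules (e.g. the
#: 3-week confirmation separation) onto the months-post-transplant axis.
DAYS_PER_MONTH = 365.25 / 12.0


def weeks_to_months(weeks: float) -> float:
    return weeks * 7.0 / DAYS_PER_MONTH


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (54.5 -> 55).

    Reported percentages use this convention; Python's built-in ``round``
    is half-to-even and would disagree on exact .5 ties.
    """
    return int(math.floor(x + 0.5))
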