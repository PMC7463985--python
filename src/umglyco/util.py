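"""Small shared helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away", "format_p"]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (print convention for p-values and fold
    changes; "0.00" is permitted)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def format_p(p: float, ndigits: int = 2) -> str:
    return f"{round_half_away(p, ndigits):.{ndigits}f}"
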