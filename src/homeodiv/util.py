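"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def percentage(count: float, total: float, ndigits: int = 0) -> float:
    """Percentage of ``count`` out of ``total``, rounded half away from zero.

    Python's built-in ``round`` uses banker's rounding; cohort summaries are
    reported with conventional half-up rounding instead (50.5% -> 51%).
    """
    if total == 0:
        raise ZeroDivisionError("percentage undefined for total == 0")
    frac = Decimal(count) / Decimal(total) * 100
    quantum = Decimal(1).scaleb(-ndigits)
    out = float(frac.quantize(quantum, rounding=ROUND_HALF_UP))
    return out


def derive_seed(base_seed: int, *streams: int) -> int:
    """Deterministic child seed below 2**31 for a named substream."""
    ss = np.random.SeedSequence([int(base_seed), *[int(s) for s in streams]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
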