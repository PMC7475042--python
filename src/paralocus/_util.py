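"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from typing import Sequence


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties (.5) away from zero.

    Python's builtin ``round`` uses banker's rounding, which would map an
    estimated 2.5 alleles to 2; allele counts here always round half up in
    magnitude instead.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def largest_remainder_split(total: int, quotas: Sequence[float]) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``quotas``.

    Uses the largest-remainder (Hamilton) method so the parts sum to ``total``
    exactly. All-zero quotas split as evenly as possible. Ties in fractional
    part are broken by earlier index, which makes the split deterministic.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    if any(q < 0 for q in quotas):
        raise ValueError("quotas must be non-negative")
    qsum = float(sum(quotas))
    if qsum == 0.0:
        shares = [total / len(quotas)] * len(quotas)
    else:
        shares = [total * q / qsum for q in quotas]
    parts = [math.floor(s) for s in shares]
    leftover = total - sum(parts)
    order = sorted(range(len(quotas)), key=lambda i: (-(shares[i] - parts[i]), i))
    for i in order[:leftover]:
        parts[i] += 1
    return parts
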