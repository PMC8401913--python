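"""Small numeric helpers shared by the reporting layers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention used in the report
    tables), avoiding binary-float surprises via the shortest decimal repr."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
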