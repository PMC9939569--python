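"""Small shared helpers: rounding and file hashing."""

from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for all reported
    percentages, as opposed to Python's banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
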