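"""Small shared helpers."""
from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as tables are conventionally typeset.

    Python's built-in ``round`` is banker's rounding (2.675 -> 2.67); report
    columns use the half-up convention instead (2.675 -> 2.68).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
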