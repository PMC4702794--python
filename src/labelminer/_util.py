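"""Shared low-level helpers: tokenization, normalization, rounding."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_WORD_RE = re.compile(r"\w+")
_SEP_RE = re.compile(r"[\s\-‐‑–—]+")


def normalize_surface(text: str) -> str:
    """Canonical dictionary key: casefold, hyphen == space, runs collapsed.

    Idempotent; leading/trailing separators are stripped.
    """
    return _SEP_RE.sub(" ", text.casefold()).strip()


def squash(key: str) -> str:
    """Separator-free form of a normalized key ("blood pressure" -> "bloodpressure")."""
    return key.replace(" ", "")


def word_tokens(text: str) -> list[str]:
    """Word tokens (maximal \\w+ runs), casefolded."""
    return [m.group(0).casefold() for m in _WORD_RE.finditer(text)]


def word_spans(text: str) -> list[tuple[int, int]]:
    """(start, end) offsets of each word token in *text*."""
    return [m.span() for m in _WORD_RE.finditer(text)]


def round_half_up(value: float, digits: int = 0) -> float:
    """Decimal half-up rounding (12.5 -> 13), immune to binary-float ties."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct_half_up(numerator: float, denominator: float, digits: int = 0) -> float | None:
    """Percentage with half-up rounding; None when the denominator is zero."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, digits)
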