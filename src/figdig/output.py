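"""Render coordinate lists as Matlab/R matrix literals or delimited text.

Numbers are written fixed-point with a configurable count of decimal
places, rounding halves away from zero (the convention spreadsheet users
expect).  Formatting always starts from the full-precision values held by
the session — changing the accuracy re-renders, it never re-rounds
already-rounded text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Literal, Tuple

from .errors import ParseError

__all__ = ["OutputSpec", "format_output", "format_number", "parse_output"]

Style = Literal["matlab", "r", "csv"]

_R_TEMPLATE = "matrix(c({body}), ncol = 2, byrow = TRUE)"
_R_PATTERN = re.compile(
    r"^\s*matrix\s*\(\s*c\s*\((?P<body>.*)\)\s*,\s*ncol\s*=\s*2\s*,"
    r"\s*byrow\s*=\s*TRUE\s*\)\s*$", re.DOTALL)


@dataclass(frozen=True)
class OutputSpec:
    """Output dialect: target grammar, decimal places, csv delimiter."""

    style: Style = "matlab"
    digits: int = 2
    delimiter: str = "\t"

    def __post_init__(self):
        if self.style not in ("matlab", "r", "csv"):
            raise ValueError(f"unknown output style {self.style!r}")
        if not 0 <= self.digits <= 15:
            raise ValueError("digits must be in 0..15")


def format_number(value: float, digits: int) -> str:
    """Fixed-point rendering with halves rounded away from zero."""
    quantum = Decimal(1).scaleb(-digits)
    # repr() gives the shortest decimal string round-tripping the float,
    # so 0.1 rounds as "0.1", not as its binary expansion.
    d = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{d:.{digits}f}"


def _pairs(points: Iterable) -> List[Tuple[float, float]]:
    out = []
    for p in points:
        if hasattr(p, "x"):
            out.append((float(p.x), float(p.y)))
        elif hasattr(p, "col"):
            out.append((float(p.col), float(p.row)))
        else:
            a, b = p
            out.append((float(a), float(b)))
    return out


def format_output(points: Iterable, spec: OutputSpec = OutputSpec()) -> str:
    """Format data points (or raw pixels) as an n-by-two matrix literal.

    matlab -> ``[x y; x y; ...]``; r -> ``matrix(c(x, y, ...), ncol = 2,
    byrow = TRUE)``; csv -> one delimited ``x<delim>y`` line per point.
    """
    pairs = _pairs(points)
    fmt = lambda v: format_number(v, spec.digits)
    if spec.style == "matlab":
        return "[" + "; ".join(f"{fmt(x)} {fmt(y)}" for x, y in pairs) + "]"
    if spec.style == "r":
        body = ", ".join(f"{fmt(x)}, {fmt(y)}" for x, y in pairs)
        return _R_TEMPLATE.format(body=body)
    return "\n".join(f"{fmt(x)}{spec.delimiter}{fmt(y)}" for x, y in pairs)


def _parse_pair(token: str, line: int) -> Tuple[float, float]:
    parts = token.split()
    if len(parts) != 2:
        raise ParseError(
            f"expected two numbers per row, got {token.strip()!r}",
            line=line)
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise ParseError(f"non-numeric row {token.strip()!r}", line=line)


def parse_output(text: str,
                 spec: OutputSpec = OutputSpec()) -> List[Tuple[float, float]]:
    """Parse text produced by :func:`format_output` back into pairs.

    ``format_output`` after ``parse_output`` is a fixed point at the
    spec's precision.
    """
    if spec.style == "matlab":
        stripped = text.strip()
        if not (stripped.startswith("[") and stripped.endswith("]")):
            raise ParseError("matlab matrix must be bracketed", line=1)
        inner = stripped[1:-1].strip()
        if not inner:
            return []
        return [_parse_pair(row, line=1) for row in inner.split(";")]
    if spec.style == "r":
        m = _R_PATTERN.match(text)
        if m is None:
            raise ParseError("not an R matrix(c(...), ncol = 2, "
                             "byrow = TRUE) literal", line=1)
        body = m.group("body").strip()
        if not body:
            return []
        try:
            values = [float(v) for v in body.split(",")]
        except ValueError:
            raise ParseError("non-numeric entry in R matrix body", line=1)
        if len(values) % 2:
            raise ParseError(
                f"odd number of values ({len(values)}) in R matrix", line=1)
        return list(zip(values[0::2], values[1::2]))
    pairs = []
    for i, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        token = raw.replace(spec.delimiter, " ")
        pairs.append(_parse_pair(token, line=i))
    return pairs
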