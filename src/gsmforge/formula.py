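"""Elemental formulas in Hill-style notation.

The grammar is deliberately narrow: an element symbol is one uppercase
letter optionally followed by one lowercase letter, with an optional
integer count (default 1).  No parentheses, dots or isotope markers —
anything outside this grammar raises :class:`FormulaError` so that exotic
annotations fail loudly instead of silently unbalancing a reaction.
"""

from __future__ import annotations

import re
from collections import Counter

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string does not fit the supported grammar."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into an element → count mapping.

    The empty string is a valid "unannotated" formula and parses to ``{}``.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    counts: Counter[str] = Counter()
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if not m or m.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r} at offset {pos}")
        element, digits = m.groups()
        counts[element] += int(digits) if digits else 1
        pos = m.end()
    return dict(counts)


def format_formula(counts: dict[str, int]) -> str:
    """Render counts in Hill order (C first, then H, then alphabetical)."""

    def hill_key(el: str) -> tuple[int, str]:
        return ({"C": 0, "H": 1}.get(el, 2), el)

    parts = []
    for el in sorted(counts, key=hill_key):
        n = counts[el]
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)
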