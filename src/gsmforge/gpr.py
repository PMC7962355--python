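"""Boolean gene-protein-reaction (GPR) expressions.

A GPR states which genes enable a reaction: AND joins members of a protein
complex (all required), OR joins isoenzymes (any suffices).  The expression
is an immutable tree of ``leaf`` / ``all_of`` / ``any_of`` nodes; the empty
expression is a distinguished value meaning "no gene association".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class GprError(ValueError):
    """Raised for malformed GPR expressions or rule strings."""


@dataclass(frozen=True)
class GprExpression:
    """A boolean gene-association tree.

    ``op`` is one of ``"leaf"``, ``"and"``, ``"or"`` or ``"empty"``.  A leaf
    carries a ``gene``; interior nodes carry ≥1 ``children``.  Instances are
    hashable and compare structurally.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op == "leaf":
            if not self.gene:
                raise GprError("GPR leaf requires a non-empty gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 1:
                raise GprError(f"GPR '{self.op}' node requires >=1 child")
        elif self.op == "empty":
            if self.gene or self.children:
                raise GprError("empty GPR carries no gene or children")
        else:
            raise GprError(f"unknown GPR node kind {self.op!r}")

    # -- constructors -------------------------------------------------

    @staticmethod
    def empty() -> "GprExpression":
        return _EMPTY

    @staticmethod
    def leaf(gene: str) -> "GprExpression":
        return GprExpression("leaf", gene=gene)

    @staticmethod
    def all_of(*children: "GprExpression") -> "GprExpression":
        return GprExpression("and", children=tuple(children)).simplify()

    @staticmethod
    def any_of(*children: "GprExpression") -> "GprExpression":
        return GprExpression("or", children=tuple(children)).simplify()

    # -- predicates ---------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        """All gene ids referenced anywhere in the tree."""
        return frozenset(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        if self.op == "leaf":
            yield self.gene  # type: ignore[misc]
        for child in self.children:
            yield from child._iter_genes()

    # -- normalisation ------------------------------------------------

    def simplify(self) -> "GprExpression":
        """Canonical form: empty children dropped, single-child interior
        nodes collapsed, same-operator children flattened, duplicate
        siblings merged, siblings sorted for determinism.

        An AND node with any empty child is empty (a complex missing a
        member cannot form); an OR node keeps its non-empty branches.
        """
        if self.op in ("leaf", "empty"):
            return self
        kids = [c.simplify() for c in self.children]
        if self.op == "and" and any(k.is_empty for k in kids):
            return _EMPTY
        kids = [k for k in kids if not k.is_empty]
        # flatten nested same-operator nodes
        flat: list[GprExpression] = []
        for k in kids:
            if k.op == self.op:
                flat.extend(k.children)
            else:
                flat.append(k)
        # dedupe, order-stable by sort key
        uniq = sorted(set(flat), key=_sort_key)
        if not uniq:
            return _EMPTY
        if len(uniq) == 1:
            return uniq[0]
        return GprExpression(self.op, children=tuple(uniq))

    # -- rendering ----------------------------------------------------

    def to_string(self) -> str:
        """Infix rendering with explicit parentheses, e.g. ``(g1 and g2) or g3``."""
        if self.op == "empty":
            return ""
        if self.op == "leaf":
            return self.gene  # type: ignore[return-value]
        joiner = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or"):
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    @staticmethod
    def from_string(rule: str) -> "GprExpression":
        """Parse an infix boolean rule (``and``/``or``, case-insensitive,
        ``&``/``|`` accepted, parentheses allowed)."""
        tokens = _tokenize(rule)
        if not tokens:
            return _EMPTY
        expr, pos = _parse_or(tokens, 0)
        if pos != len(tokens):
            raise GprError(f"trailing tokens in GPR rule {rule!r}")
        return expr.simplify()


def _sort_key(e: GprExpression) -> tuple:
    if e.op == "leaf":
        return (0, e.gene, "")
    return (1, e.op, e.to_string())


_EMPTY = GprExpression("empty")


# -- infix parser -----------------------------------------------------

def _tokenize(rule: str) -> list[str]:
    out: list[str] = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            out.append(ch)
            i += 1
        elif ch == "&":
            out.append("and")
            i += 1 + (i + 1 < n and rule[i + 1] == "&")
        elif ch == "|":
            out.append("or")
            i += 1 + (i + 1 < n and rule[i + 1] == "|")
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()&|":
                j += 1
            word = rule[i:j]
            low = word.lower()
            out.append(low if low in ("and", "or") else word)
            i = j
    return out


def _parse_or(tokens: list[str], pos: int) -> tuple[GprExpression, int]:
    left, pos = _parse_and(tokens, pos)
    branches = [left]
    while pos < len(tokens) and tokens[pos] == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        branches.append(nxt)
    if len(branches) == 1:
        return left, pos
    return GprExpression("or", children=tuple(branches)), pos


def _parse_and(tokens: list[str], pos: int) -> tuple[GprExpression, int]:
    left, pos = _parse_atom(tokens, pos)
    parts = [left]
    while pos < len(tokens) and tokens[pos] == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        parts.append(nxt)
    if len(parts) == 1:
        return left, pos
    return GprExpression("and", children=tuple(parts)), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[GprExpression, int]:
    if pos >= len(tokens):
        raise GprError("unexpected end of GPR rule")
    tok = tokens[pos]
    if tok == "(":
        expr, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GprError("unbalanced parenthesis in GPR rule")
        return expr, pos + 1
    if tok in (")", "and", "or"):
        raise GprError(f"unexpected token {tok!r} in GPR rule")
    return GprExpression.leaf(tok), pos + 1
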