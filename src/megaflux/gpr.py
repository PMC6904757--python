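"""Gene-protein-reaction (GPR) Boolean expressions.

A GPR associates a reaction with the genes whose products catalyze it:
``and`` joins subunits of a complex (all required), ``or`` joins isozymes
(any one suffices).  An empty expression means the reaction has no gene
association (spontaneous/orphan) and is always considered active.

Grammar: ``or`` has the lowest precedence, ``and`` binds tighter,
parentheses group; keywords are case-insensitive and any other token is a
gene identifier.  Associative chains are flattened, so ``g1 and g2 and g3``
parses to a single three-child AND node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import FrozenSet, Iterable, Set, Tuple

__all__ = ["GPRExpression", "GPRSyntaxError", "parse_gpr", "gpr_active"]


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene-id leaves.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``.  Leaves
    carry the gene id in ``gene``; internal nodes carry >= 2 children.
    """

    op: str = "empty"
    gene: str | None = None
    children: Tuple["GPRExpression", ...] = field(default_factory=tuple)

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> FrozenSet[str]:
        """All gene ids appearing in the expression."""
        if self.op == "gene":
            return frozenset({self.gene})  # type: ignore[arg-type]
        out: Set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def active(self, deleted: Iterable[str] = ()) -> bool:
        """Evaluate with the given genes knocked out.

        AND nodes need every child active, OR nodes any child; an empty
        expression is always active (no gene gates the reaction).
        """
        deleted = set(deleted)
        if self.op == "empty":
            return True
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.active(deleted) for c in self.children)
        return any(c.active(deleted) for c in self.children)

    def to_string(self) -> str:
        """Canonical serialization; round-trips through :func:`parse_gpr`."""
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesize ORs under an AND; gene leaves never need parens
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_GPR = GPRExpression()

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None:
            break
        tokens.append((match.group(1), match.start(1)))
        pos = match.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.idx = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.idx] if self.idx < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        token = self.tokens[self.idx]
        self.idx += 1
        return token

    def parse(self) -> GPRExpression:
        expr = self.parse_or()
        leftover = self.peek()
        if leftover is not None:
            raise GPRSyntaxError(f"unexpected token {leftover[0]!r}", leftover[1])
        return expr

    def parse_or(self) -> GPRExpression:
        children = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[0].lower() == "or":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else _flatten("or", children)

    def parse_and(self) -> GPRExpression:
        children = [self.parse_atom()]
        while (tok := self.peek()) is not None and tok[0].lower() == "and":
            self.next()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else _flatten("and", children)

    def parse_atom(self) -> GPRExpression:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError("expected gene id or '('", len(self.text))
        text, offset = self.next()
        if text == "(":
            inner = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GPRSyntaxError("unbalanced parenthesis", offset)
            self.next()
            return inner
        if text == ")" or text.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {text!r}", offset)
        return GPRExpression(op="gene", gene=text)


def _flatten(op: str, children: list[GPRExpression]) -> GPRExpression:
    flat: list[GPRExpression] = []
    for child in children:
        if child.op == op:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GPRExpression(op=op, children=tuple(flat))


def parse_gpr(text: str) -> GPRExpression:
    """Parse a GPR string such as ``"(g1 and g2) or g3"``.

    The empty string yields the empty expression (no gene association).
    Raises :class:`GPRSyntaxError` naming the character offset on
    unbalanced parentheses or stray tokens.
    """
    if text is None or not text.strip():
        return EMPTY_GPR
    return _Parser(text).parse()


def gpr_active(gpr: GPRExpression, deleted: Iterable[str] = ()) -> bool:
    """True when the reaction gated by ``gpr`` remains catalyzable after
    deleting the given genes."""
    return gpr.active(deleted)


def truth_table(gpr: GPRExpression) -> dict[tuple[str, ...], bool]:
    """Exhaustive evaluation over all present/deleted assignments of the
    expression's genes; used as an oracle in tests (<= 2^n rows)."""
    genes = sorted(gpr.genes())
    table: dict[tuple[str, ...], bool] = {}
    for mask in product((False, True), repeat=len(genes)):
        deleted = tuple(g for g, dead in zip(genes, mask) if dead)
        table[deleted] = gpr.active(set(deleted))
    return table
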