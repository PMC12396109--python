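"""Gene-protein-reaction (GPR) rules: parsing, rendering and boolean evaluation.

A GPR rule is a boolean expression over gene identifiers stating which gene
products enable a reaction, e.g. ``(g1 and g2) or g3`` for an isozyme pair
where one member is a two-subunit complex.  Evaluation against a set of
*present* (expressed) genes decides whether the reaction is supported in a
given condition.

Accepted connective dialects: ``and``/``or`` (any case) and ``&&``/``||``;
``and`` binds tighter than ``or``.  Rules are normalized to lower-case
``and``/``or`` on rendering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

__all__ = ["GprError", "Gene", "BoolOp", "GprExpression", "parse_gpr", "evaluate_gpr"]


class GprError(ValueError):
    """Raised for malformed GPR text (position of the offending token included)."""


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    name: str

    def genes(self) -> frozenset[str]:
        return frozenset([self.name])

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        return self.name in present

    def render(self) -> str:
        return self.name


@dataclass(frozen=True)
class BoolOp:
    """Internal node: an n-ary ``and`` / ``or`` over child expressions."""

    op: str  # "and" | "or"
    children: tuple["GprExpression", ...]

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def render(self) -> str:
        parts = []
        for c in self.children:
            text = c.render()
            # parenthesize an "or" nested under an "and" to preserve precedence
            if self.op == "and" and isinstance(c, BoolOp) and c.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


GprExpression = Union[Gene, BoolOp]

_TOKEN = re.compile(r"\(|\)|&&|\|\||[^\s()]+")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    for m in _TOKEN.finditer(text):
        tok = m.group(0)
        low = tok.lower()
        if tok == "&&":
            tok = "and"
        elif tok == "||":
            tok = "or"
        elif low in ("and", "or"):
            tok = low
        yield tok, m.start()


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR at position {len(self.text)}: {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        expr = self.or_expr()
        extra = self.peek()
        if extra is not None:
            raise GprError(f"unexpected token {extra[0]!r} at position {extra[1]} in {self.text!r}")
        return expr

    def or_expr(self) -> GprExpression:
        children = [self.and_expr()]
        while self.peek() is not None and self.peek()[0] == "or":
            self.take()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def and_expr(self) -> GprExpression:
        children = [self.atom()]
        while self.peek() is not None and self.peek()[0] == "and":
            self.take()
            children.append(self.atom())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def atom(self) -> GprExpression:
        tok, start = self.take()
        if tok == "(":
            inner = self.or_expr()
            nxt = self.peek()
            if nxt is None or nxt[0] != ")":
                raise GprError(f"unbalanced parenthesis opened at position {start} in {self.text!r}")
            self.take()
            return inner
        if tok in (")", "and", "or"):
            raise GprError(f"unexpected token {tok!r} at position {start} in {self.text!r}")
        return Gene(tok.strip())


def parse_gpr(text: str) -> GprExpression | None:
    """Parse GPR text into an expression tree; empty/blank text parses to ``None``.

    ``and`` binds tighter than ``or``; parentheses override.  Raises
    :class:`GprError` with the character position for unbalanced parentheses
    or dangling connectives.
    """
    if text is None or not text.strip():
        return None
    return _Parser(text).parse()


def evaluate_gpr(expr: GprExpression | None, present: set[str] | frozenset[str]) -> bool | None:
    """Evaluate a GPR tree against a set of present genes.

    Returns ``None`` for an absent rule (``expr is None``): GPR-less reactions
    (exchanges, biomass, spontaneous) are neither supported nor contradicted
    by expression evidence and are scored separately downstream.
    """
    if expr is None:
        return None
    return expr.evaluate(present)
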