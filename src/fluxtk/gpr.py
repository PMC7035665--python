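"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene combinations enable a reaction: ``and`` joins
subunits of a complex (all required), ``or`` joins isozymes (any suffices).
Rules are parsed from the COBRA-style string convention — case-insensitive
``and``/``or``, parentheses, gene ids as arbitrary non-whitespace tokens
other than the operators. ``not`` never appears in metabolic GPRs and is
rejected as a plain gene id would be suspicious; we simply treat it as an id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Union

__all__ = ["GPRRule", "GPRParseError"]

# Expression tree: a leaf is a gene id (str); an internal node is
# ("and"|"or", [children]).  Kept as plain tuples for cheap equality/hashing.
Node = Union[str, tuple]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


def _tokenize(text: str) -> Iterator[str]:
    buf = []
    for ch in text:
        if ch in "()":
            if buf:
                yield "".join(buf)
                buf = []
            yield ch
        elif ch.isspace():
            if buf:
                yield "".join(buf)
                buf = []
        else:
            buf.append(ch)
    if buf:
        yield "".join(buf)


class _Parser:
    """Recursive-descent parser for  expr := term (OR term)* ;
    term := factor (AND factor)* ; factor := '(' expr ')' | GENE."""

    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.pos = 0
        self.text = text

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise GPRParseError(
                f"trailing token {self.peek()!r} in GPR rule: {self.text!r}"
            )
        return node

    def expr(self) -> Node:
        parts = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def term(self) -> Node:
        parts = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def factor(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            closing = self.next()
            if closing != ")":
                raise GPRParseError(f"expected ')' in GPR rule: {self.text!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(
                f"unexpected token {tok!r} in GPR rule: {self.text!r}"
            )
        return tok


@dataclass(frozen=True)
class GPRRule:
    """A parsed GPR expression tree; ``root is None`` means the empty rule
    (reaction not gene-associated, always enabled)."""

    root: Optional[Node] = None

    @classmethod
    def parse(cls, text: str) -> "GPRRule":
        text = (text or "").strip()
        if not text:
            return cls(None)
        return cls(_Parser(text).parse())

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset:
        """Set of gene ids referenced anywhere in the rule."""

        if self.root is None:
            return frozenset()
        out = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.add(node)
            else:
                stack.extend(node[1])
        return frozenset(out)

    def evaluate(self, deleted: frozenset | set = frozenset()) -> bool:
        """Boolean value with genes in ``deleted`` set False, all others True.

        The empty rule evaluates True: a reaction without gene association
        cannot be disabled by any gene deletion.
        """

        def ev(node: Node) -> bool:
            if isinstance(node, str):
                return node not in deleted
            op, children = node
            if op == "and":
                return all(ev(c) for c in children)
            return any(ev(c) for c in children)

        return True if self.root is None else ev(self.root)

    def aggregate(self, scores: dict, missing: float = 0.0) -> float:
        """Map per-gene expression scores onto the rule: AND -> min of the
        operands (a complex is limited by its scarcest subunit), OR -> max
        (isozymes are interchangeable). The empty rule scores +inf: absence
        of gene evidence is not evidence of absence."""

        def ag(node: Node) -> float:
            if isinstance(node, str):
                return float(scores.get(node, missing))
            op, children = node
            vals = [ag(c) for c in children]
            return min(vals) if op == "and" else max(vals)

        return float("inf") if self.root is None else ag(self.root)

    def to_string(self) -> str:
        def ser(node: Node, parent_op: Optional[str] = None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(ser(c, op) for c in children)
            # parenthesize 'or' under 'and' (and any nested mixed grouping)
            if parent_op is not None and parent_op != op:
                return f"({joined})"
            return joined

        return "" if self.root is None else ser(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()
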