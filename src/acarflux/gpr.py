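"""Gene-protein-reaction (GPR) boolean rules.

A GPR states which combinations of genes suffice to catalyse a reaction,
e.g. ``"(g1 and g2) or g3"`` for an isozyme of a two-subunit complex.
The grammar is infix with parentheses and case-insensitive AND/OR; NOT is
not part of the genre and is rejected.  An empty rule means the reaction
has no gene association and is always catalysable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Tuple, Union

__all__ = ["GPR", "GPRSyntaxError"]


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


# expression tree: gene literal (str) or ("and"|"or", (child, child, ...))
Node = Union[str, Tuple[str, Tuple["Node", ...]]]

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GPRSyntaxError(f"unexpected character at {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser: or_expr := and_expr ('or' and_expr)*."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise GPRSyntaxError(f"trailing tokens at {self.peek()!r}")
        return node

    def or_expr(self) -> Node:
        parts = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    def and_expr(self) -> Node:
        parts = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def atom(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.or_expr()
            if self.next() != ")":
                raise GPRSyntaxError("unbalanced parentheses")
            return node
        if tok == ")":
            raise GPRSyntaxError("unbalanced parentheses")
        if tok.lower() in ("and", "or", "not"):
            raise GPRSyntaxError(f"misplaced operator {tok!r}")
        return tok


def _collect_genes(node: Node) -> frozenset[str]:
    if isinstance(node, str):
        return frozenset([node])
    _, children = node
    out: set[str] = set()
    for child in children:
        out |= _collect_genes(child)
    return frozenset(out)


def _eval(node: Node, deleted: frozenset[str]) -> bool:
    if isinstance(node, str):
        return node not in deleted
    op, children = node
    if op == "and":
        return all(_eval(c, deleted) for c in children)
    if op == "or":
        return any(_eval(c, deleted) for c in children)
    raise GPRSyntaxError(f"malformed node {op!r}")


def _to_string(node: Node, parent: str | None = None) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    inner = f" {op} ".join(_to_string(c, op) for c in children)
    # parenthesize AND groups inside OR context and vice versa for clarity
    if parent is not None and parent != op:
        return f"({inner})"
    return inner


@dataclass(frozen=True)
class GPR:
    """A parsed gene-protein-reaction rule.

    ``GPR.empty()`` (tree ``None``) always evaluates to True: a reaction
    without gene association cannot be disabled by gene deletions.
    """

    tree: Node | None = None
    genes: FrozenSet[str] = field(default=frozenset())

    @classmethod
    def empty(cls) -> "GPR":
        return cls(None, frozenset())

    @classmethod
    def parse(cls, text: str | None) -> "GPR":
        if text is None or not text.strip():
            return cls.empty()
        tree = _Parser(_tokenize(text)).parse()
        return cls(tree, _collect_genes(tree))

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True iff the reaction is still catalysable after deleting *deleted*."""
        if self.tree is None:
            return True
        return _eval(self.tree, frozenset(deleted))

    def to_string(self) -> str:
        return "" if self.tree is None else _to_string(self.tree)

    def __bool__(self) -> bool:
        return self.tree is not None
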