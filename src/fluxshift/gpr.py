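"""Gene–protein–reaction (GPR) rules.

A GPR is a boolean expression over gene symbols ("G1 and (G2 or G3)")
stating which gene products are needed for a reaction to be catalysed.
Here the rules are evaluated in two modes:

* over the ordered expression states −1 < 0 < +1 (lowly / moderately /
  highly expressed), with AND → min and OR → max — the standard way of
  lifting gene-level expression states to the reaction level;
* over plain booleans (gene present / absent), used for gene-level
  knockouts.

Rules are parsed once into immutable expression trees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

__all__ = ["GPRParseError", "Gene", "BoolOp", "GPR", "parse_gpr"]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gene:
    symbol: str

    def __str__(self) -> str:
        return self.symbol


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple["Node", ...]

    def __str__(self) -> str:
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            s = str(child)
            if isinstance(child, BoolOp) and child.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


Node = Union[Gene, BoolOp]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


class GPR:
    """A parsed gene–protein–reaction rule."""

    __slots__ = ("root", "_genes", "_text")

    def __init__(self, root: Node):
        self.root = root
        self._genes = frozenset(g.symbol for g in _iter_genes(root))
        self._text = str(root)

    @property
    def genes(self) -> frozenset[str]:
        return self._genes

    def __str__(self) -> str:
        return self._text

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GPR({self._text!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GPR) and self.root == other.root

    def __hash__(self) -> int:
        return hash(self.root)

    def evaluate_states(self, states: Mapping[str, int], default: int = 0) -> int:
        """Evaluate over ordered states in {−1, 0, +1}; AND=min, OR=max.

        Genes absent from ``states`` take ``default`` (no evidence → moderate).
        """
        return _eval_states(self.root, states, default)

    def evaluate_bool(self, present: Mapping[str, bool], default: bool = True) -> bool:
        """Evaluate with genes as booleans (catalysis possible or not)."""
        return _eval_bool(self.root, present, default)


def _iter_genes(node: Node) -> Iterator[Gene]:
    if isinstance(node, Gene):
        yield node
    else:
        for child in node.children:
            yield from _iter_genes(child)


def _eval_states(node: Node, states: Mapping[str, int], default: int) -> int:
    if isinstance(node, Gene):
        return states.get(node.symbol, default)
    vals = (_eval_states(c, states, default) for c in node.children)
    return min(vals) if node.op == "and" else max(vals)


def _eval_bool(node: Node, present: Mapping[str, bool], default: bool) -> bool:
    if isinstance(node, Gene):
        return present.get(node.symbol, default)
    vals = (_eval_bool(c, present, default) for c in node.children)
    return all(vals) if node.op == "and" else any(vals)


def parse_gpr(text: str) -> GPR:
    """Parse a GPR string.

    Grammar: gene symbols, ``and``, ``or`` (case-insensitive) and
    parentheses.  ``or`` binds looser than ``and``, as in cobra.
    """
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise GPRParseError("empty GPR string")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Node:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def parse_and() -> Node:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def parse_atom() -> Node:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return Gene(take())

    root = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    return GPR(root)
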