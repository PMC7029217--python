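"""Gene-protein-reaction (GPR) rules.

A GPR rule is a Boolean expression over gene ids: ``and`` means an enzyme
complex (all subunits required), ``or`` means isozymes (any one suffices).
Single-gene deletions disable a reaction only when the whole expression
evaluates false with that gene set to false.  The same tree is reused by
the E-Flux integration, where ``and`` takes the minimum of child scores
(complex limited by its scarcest subunit) and ``or`` sums them (isozyme
capacities add).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple, Union

MISSING = -1.0  # sentinel expression score for genes without data


class GPRSyntaxError(ValueError):
    """Raised for rules that do not parse."""


@dataclass(frozen=True)
class GPRExpression:
    """AST node: a leaf gene, or an AND/OR over children.

    ``op`` is None for a leaf (then ``gene`` is set) and "and"/"or" for an
    internal node.  The empty expression (``gene`` and ``op`` both None)
    denotes a reaction with no gene requirement.
    """

    op: Optional[str] = None
    gene: Optional[str] = None
    children: Tuple["GPRExpression", ...] = ()

    @property
    def is_empty(self) -> bool:
        return self.op is None and self.gene is None

    def genes(self) -> FrozenSet[str]:
        if self.gene is not None:
            return frozenset([self.gene])
        out: Set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def to_string(self) -> str:
        """Normalized serialization: explicit parentheses around OR under AND."""
        if self.is_empty:
            return ""
        if self.gene is not None:
            return self.gene
        parts = []
        for child in self.children:
            text = child.to_string()
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> List[str]:
    tokens = _TOKEN.findall(rule)
    if "".join(tokens).replace(" ", "") != rule.replace(" ", ""):
        raise GPRSyntaxError(f"cannot tokenize GPR rule {rule!r}")
    return tokens


def parse_gpr(rule: str) -> GPRExpression:
    """Parse a rule like ``g1 and (g2 or g3)``.

    ``and`` binds tighter than ``or`` (so ``a or b and c`` is
    ``a or (b and c)``); operator keywords are case-insensitive; anything
    else is a gene id.
    """
    rule = (rule or "").strip()
    if not rule:
        return GPRExpression()
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRExpression(op="or", children=tuple(terms))

    def parse_and() -> GPRExpression:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GPRExpression(op="and", children=tuple(factors))

    def parse_atom() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule in {rule!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in {rule!r}")
            take()
            return inner
        if tok == ")":
            raise GPRSyntaxError(f"unbalanced parentheses in {rule!r}")
        if tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"operator {tok!r} where a gene was expected in {rule!r}")
        return GPRExpression(gene=take())

    expr = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens {tokens[pos:]} in {rule!r}")
    return expr


def evaluate_gpr(ast: GPRExpression, deleted_genes: Union[Set[str], FrozenSet[str], Sequence[str]]) -> bool:
    """True iff the reaction stays active with ``deleted_genes`` knocked out.

    An empty expression is always active (orphan reactions are never
    disabled by a gene deletion).
    """
    deleted = set(deleted_genes)
    if ast.is_empty:
        return True
    if ast.gene is not None:
        return ast.gene not in deleted
    values = [evaluate_gpr(child, deleted) for child in ast.children]
    return all(values) if ast.op == "and" else any(values)


def score_gpr(ast: GPRExpression, expression: Mapping[str, float]) -> float:
    """Map per-gene expression onto one reaction activity score.

    AND -> min over scored children, OR -> sum over scored children.  The
    sentinel ``-1`` marks missing data: an AND ignores missing children
    when at least one child is scored, an OR sums only scored children;
    a node with no scored child, and the empty expression, score ``-1``.
    """
    if ast.is_empty:
        return MISSING
    if ast.gene is not None:
        value = expression.get(ast.gene, MISSING)
        return value if value >= 0 else MISSING
    scored = [
        s for s in (score_gpr(child, expression) for child in ast.children)
        if s != MISSING
    ]
    if not scored:
        return MISSING
    return min(scored) if ast.op == "and" else sum(scored)
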