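"""Gene-protein-reaction rules and expression-derived flux bounds.

Converts boolean GPR strings into expression trees, evaluates them against a
condition's gene expression values to obtain per-column flux caps f(g_j)
(E-flux semantics: AND -> min over complex subunits, OR -> sum over
isoenzymes), computes the per-column normalizers M_j, and lifts gene-gene
network edges to the reaction-pair set R that the quadratic objective sums
over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .coexpr_net import CoexpressionNetwork, ExpressionMatrix
    from .model_io import IrreversibleTemplate

__all__ = [
    "GPRNode",
    "ReactionBounds",
    "ReactionPairSet",
    "parse_gpr",
    "eval_gpr_bound",
    "gpr_genes",
    "reaction_bounds_for_condition",
    "build_pair_set",
]


# ---------------------------------------------------------------------------
# GPR parsing (recursive descent over and/or/parentheses)
# ---------------------------------------------------------------------------

@dataclass
class GPRNode:
    op: str  # "and" | "or" | "leaf" | "empty"
    children: list["GPRNode"] = field(default_factory=list)
    gene: str | None = None

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        if self.op == "leaf":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out


class GPRParseError(ValueError):
    pass


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(rule):
        ch = rule[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < len(rule) and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            tokens.append((rule[i:j], i))
            i = j
    return tokens


def parse_gpr(rule: str) -> GPRNode:
    """Parse a GPR string like ``(g1 and g2) or g3`` into an expression tree.

    ``or`` binds looser than ``and``; an empty string yields the empty
    sentinel node.  Raises :class:`GPRParseError` with the offending position
    on malformed input.
    """
    if not rule or not rule.strip():
        return GPRNode("empty")
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GPRNode:
        nonlocal pos
        terms = [parse_and()]
        while (t := peek()) is not None and t[0].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRNode("or", terms)

    def parse_and() -> GPRNode:
        nonlocal pos
        factors = [parse_atom()]
        while (t := peek()) is not None and t[0].lower() == "and":
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GPRNode("and", factors)

    def parse_atom() -> GPRNode:
        nonlocal pos
        t = peek()
        if t is None:
            raise GPRParseError(f"unexpected end of GPR rule {rule!r}")
        tok, at = t
        if tok == "(":
            pos += 1
            node = parse_or()
            t2 = peek()
            if t2 is None or t2[0] != ")":
                raise GPRParseError(
                    f"unbalanced parenthesis opened at position {at} in {rule!r}"
                )
            pos += 1
            return node
        if tok == ")" or tok.lower() in {"and", "or"}:
            raise GPRParseError(
                f"unexpected token {tok!r} at position {at} in {rule!r}"
            )
        pos += 1
        return GPRNode("leaf", gene=tok)

    tree = parse_or()
    if pos != len(tokens):
        tok, at = tokens[pos]
        raise GPRParseError(f"stray token {tok!r} at position {at} in {rule!r}")
    return tree


def gpr_genes(rule: str) -> set[str]:
    """Gene identifiers referenced by a GPR string."""
    tree = parse_gpr(rule)
    return set() if tree.is_empty else tree.genes()


# ---------------------------------------------------------------------------
# E-flux bound evaluation
# ---------------------------------------------------------------------------

def eval_gpr_bound(
    tree: GPRNode,
    expr: Mapping[str, float] | Callable[[str], float | None],
    T: float,
) -> float:
    """Evaluate a GPR tree against expression values to a flux bound.

    AND nodes take the minimum of their children (a complex is limited by
    its scarcest subunit), OR nodes the sum (isoenzymes add capacity), and
    leaves the gene's expression value.  The empty tree returns T.  Genes
    missing from ``expr`` are dropped from their parent node; a tree whose
    every leaf is unmeasured evaluates to T (treated as unmapped).
    """
    lookup = expr.get if isinstance(expr, Mapping) else expr

    def ev(node: GPRNode) -> float | None:
        if node.op == "leaf":
            val = lookup(node.gene)
            if val is None:
                return None
            if val < 0:
                raise ValueError(
                    f"negative expression value {val} for gene {node.gene!r}"
                )
            return float(val)
        vals = [v for v in (ev(c) for c in node.children) if v is not None]
        if not vals:
            return None
        return min(vals) if node.op == "and" else sum(vals)

    if tree.is_empty:
        return T
    out = ev(tree)
    return T if out is None else out


# ---------------------------------------------------------------------------
# Per-condition reaction bounds
# ---------------------------------------------------------------------------

@dataclass
class ReactionBounds:
    """Per-column E-flux bounds f and normalizers M for one condition.

    ``unmapped`` marks columns whose GPR is empty or entirely unmeasured;
    they keep the template bound T and are excluded from the quadratic
    objective.  Forward/backward siblings of a reversible reaction share f
    and M by construction.
    """

    condition: str
    f: np.ndarray
    M: np.ndarray
    unmapped: set[int] = field(default_factory=set)

    def mapped_columns(self) -> list[int]:
        return [
            j
            for j in range(len(self.f))
            if j not in self.unmapped and self.M[j] > 0
        ]


def reaction_bounds_for_condition(
    template: "IrreversibleTemplate",
    expression: "ExpressionMatrix",
    condition: str,
    T: float | None = None,
) -> ReactionBounds:
    """Compute f (selected condition) and M (max over all conditions).

    M_j is the maximum over every condition of the GPR-evaluated bound for
    column j, so the transformed flux q_j = 1 + v_j/M_j lies in [1, 2]
    whenever v_j <= f(g_j) <= M_j.
    """
    if condition not in expression.conditions:
        raise KeyError(f"condition {condition!r} not in expression matrix")
    T = template.T if T is None else T

    conditions = list(expression.conditions)
    col_gprs = template.column_gpr()
    n_cols = template.n_columns
    f = np.empty(n_cols)
    M = np.empty(n_cols)
    unmapped: set[int] = set()

    cache: dict[str, tuple[float, float, bool]] = {}
    gene_set = set(expression.genes)
    for j, rule in enumerate(col_gprs):
        if rule not in cache:
            tree = parse_gpr(rule)
            if tree.is_empty or not (tree.genes() & gene_set):
                cache[rule] = (T, T, True)
            else:
                per_cond = [
                    eval_gpr_bound(tree, expression.condition_values(c), T)
                    for c in conditions
                ]
                f_j = per_cond[conditions.index(condition)]
                cache[rule] = (f_j, max(per_cond), False)
        f_j, M_j, is_unmapped = cache[rule]
        f[j], M[j] = f_j, M_j
        if is_unmapped:
            unmapped.add(j)
    return ReactionBounds(condition=condition, f=f, M=M, unmapped=unmapped)


# ---------------------------------------------------------------------------
# Lifting network edges to reaction pairs
# ---------------------------------------------------------------------------

@dataclass
class ReactionPairSet:
    """The unordered column-pair set R the quadratic objective sums over."""

    pairs: set[tuple[int, int]]
    provenance: dict[tuple[int, int], list[tuple[str, str]]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.pairs)


def build_pair_set(
    network: "CoexpressionNetwork",
    template: "IrreversibleTemplate",
    bounds: ReactionBounds,
) -> ReactionPairSet:
    """Lift gene-gene network edges to the reaction-pair set R.

    For every network edge (a, b), every unordered pair of distinct mapped
    columns (i, j) with a on reaction i and b on reaction j joins R.  Pairs
    that are a forward/backward sibling pair of one reversible reaction are
    excluded (they are already bound by the complementarity constraint), as
    are self-pairs and columns with M_j = 0 or no usable GPR.
    """
    mapped = set(bounds.mapped_columns())
    col_gprs = template.column_gpr()
    gene_to_cols: dict[str, list[int]] = {}
    for j, rule in enumerate(col_gprs):
        if j not in mapped:
            continue
        for g in gpr_genes(rule):
            gene_to_cols.setdefault(g, []).append(j)

    rev = {frozenset(p) for p in template.rev_pairs}
    pairs: set[tuple[int, int]] = set()
    provenance: dict[tuple[int, int], list[tuple[str, str]]] = {}

    n_edges_used = 0
    for a, b in network.edges():
        cols_a = gene_to_cols.get(a, ())
        cols_b = gene_to_cols.get(b, ())
        if cols_a and cols_b:
            n_edges_used += 1
        for i in cols_a:
            for j in cols_b:
                if i == j or frozenset((i, j)) in rev:
                    continue
                key = (min(i, j), max(i, j))
                pairs.add(key)
                provenance.setdefault(key, []).append((a, b))

    if n_edges_used == 0:
        warnings.warn(
            "no network edge maps onto model reactions; R is empty and the "
            "solve degenerates to an E-flux-feasible solution"
        )
    result = ReactionPairSet(pairs=pairs, provenance=provenance)
    assert all(i != j for i, j in result.pairs)
    assert not any(frozenset(p) in rev for p in result.pairs)
    return result
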