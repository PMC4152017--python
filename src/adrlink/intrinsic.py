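"""Intrinsic similarity features: taxonomy semantic similarity and blending.

Intrinsic similarities come from outside the association network: chemical
structure scores between drugs, the ATC classification taxonomy of drugs,
and the MedDRA taxonomy of adverse reactions.  Precomputed pair scores are
loaded through :mod:`adrlink.network_io`; this module computes semantic
similarity over a term hierarchy from scratch, and blends similarity
matrices by convex combination (e.g. ``omega * chemical + (1-omega) * ATC``
for the drug side, or ``lambda * topological + (1-lambda) * intrinsic``
for integrated features).

Semantic similarity uses Lin's information-content measure with
descendant-count IC: ``IC(t) = -ln(desc(t) / desc(root))`` where ``desc``
counts a term plus all of its descendants, and

    sim(t1, t2) = 2 * IC(best common ancestor) / (IC(t1) + IC(t2)).

A node annotated with several terms scores against another node as the
maximum over its term pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .types import SimilarityMatrix

import numpy as np


@dataclass
class Taxonomy:
    """Rooted term hierarchy (DAG) with node-to-term annotations.

    Parameters
    ----------
    parents
        Mapping term -> set of parent terms.  Exactly one term (the root)
        has no parent; every term must reach the root.
    annotations
        Mapping node label -> set of terms the node is annotated with.
    """

    parents: dict[str, set[str]]
    annotations: dict[str, set[str]]
    _desc_count: dict[str, int] = field(default_factory=dict, repr=False)
    _ancestors: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        terms = set(self.parents)
        for ps in self.parents.values():
            terms.update(ps)
        self.parents = {t: set(self.parents.get(t, set())) for t in terms}
        roots = [t for t, ps in self.parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._check_acyclic()
        children: dict[str, set[str]] = {t: set() for t in terms}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        self._children = children
        for node, ts in self.annotations.items():
            missing = set(ts) - terms
            if missing:
                raise ValueError(f"node {node!r} annotated with unknown terms {missing}")
            if not ts:
                raise ValueError(f"node {node!r} has no term annotation")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for p in self.parents[t]:
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"taxonomy contains a cycle through {p!r}")
                if s == 0:
                    visit(p, stack)
            state[t] = 2

        for t in self.parents:
            if state.get(t, 0) == 0:
                visit(t, [])

    def descendants_count(self, term: str) -> int:
        """Number of terms in the subtree rooted at ``term`` (inclusive)."""
        if term not in self._desc_count:
            seen: set[str] = set()
            stack = [term]
            while stack:
                t = stack.pop()
                if t in seen:
                    continue
                seen.add(t)
                stack.extend(self._children[t])
            self._desc_count[term] = len(seen)
        return self._desc_count[term]

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term``, including the term itself."""
        if term not in self._ancestors:
            seen: set[str] = set()
            stack = [term]
            while stack:
                t = stack.pop()
                if t in seen:
                    continue
                seen.add(t)
                stack.extend(self.parents[t])
            self._ancestors[term] = seen
        return self._ancestors[term]

    def ic(self, term: str) -> float:
        """Information content -ln(desc(term) / desc(root))."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        total = self.descendants_count(self.root)
        return -math.log(self.descendants_count(term) / total)

    def term_similarity(self, t1: str, t2: str) -> float:
        """Lin similarity between two terms, in [0, 1]."""
        common = self.ancestors(t1) & self.ancestors(t2)
        ic_lca = max(self.ic(t) for t in common)
        denom = self.ic(t1) + self.ic(t2)
        if denom == 0.0:
            # degenerate hierarchy where both terms carry no information
            return 1.0 if t1 == t2 else 0.0
        return 2.0 * ic_lca / denom


def semantic_similarity(tax: Taxonomy, a: str, b: str) -> float:
    """Semantic similarity between two annotated nodes, in [0, 1].

    The node-level score is the maximum Lin similarity over all pairs of
    the nodes' annotated terms.
    """
    for node in (a, b):
        if node not in tax.annotations:
            raise KeyError(f"node {node!r} has no term mapping")
    return max(
        tax.term_similarity(t1, t2)
        for t1 in tax.annotations[a]
        for t2 in tax.annotations[b]
    )


def semantic_similarity_matrix(
    tax: Taxonomy, ids: tuple[str, ...], side: str, source: str
) -> SimilarityMatrix:
    """Pairwise semantic similarity over ``ids``; diagonal forced to 1."""
    k = len(ids)
    S = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            S[i, j] = S[j, i] = semantic_similarity(tax, ids[i], ids[j])
    return SimilarityMatrix(side=side, source=source, ids=tuple(ids), S=S)


def read_taxonomy(parent_child_path: str | Path, mapping_path: str | Path) -> Taxonomy:
    """Load a taxonomy from a parent-child TSV and a node-to-term TSV.

    ``parent_child_path``: two columns ``parent<TAB>child``.
    ``mapping_path``: two columns ``node<TAB>term`` (one record per term).
    """
    parents: dict[str, set[str]] = {}
    with open(parent_child_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{parent_child_path}:{lineno}: expected 2 fields")
            parent, child = fields
            parents.setdefault(parent, set())
            parents.setdefault(child, set()).add(parent)
    annotations: dict[str, set[str]] = {}
    with open(mapping_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{mapping_path}:{lineno}: expected 2 fields")
            node, term = fields
            annotations.setdefault(node, set()).add(term)
    return Taxonomy(parents=parents, annotations=annotations)


def blend_similarities(
    mats: list[SimilarityMatrix], weights: list[float]
) -> SimilarityMatrix:
    """Elementwise convex combination of aligned similarity matrices.

    All matrices must share side and id order; weights must be
    non-negative and sum to 1 (within 1e-9).
    """
    if not mats:
        raise ValueError("need at least one matrix to blend")
    if len(mats) != len(weights):
        raise ValueError("number of weights must match number of matrices")
    w = np.asarray(weights, dtype=np.float64)
    if (w < 0).any():
        raise ValueError("blend weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"blend weights must sum to 1, got {w.sum()}")
    ref = mats[0]
    for m in mats[1:]:
        if m.side != ref.side:
            raise ValueError("cannot blend matrices from different sides")
        if m.ids != ref.ids:
            raise ValueError("cannot blend matrices with different id orders")
    S = sum(wi * m.S for wi, m in zip(w, mats))
    return SimilarityMatrix(side=ref.side, source="blended", ids=ref.ids, S=S)
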