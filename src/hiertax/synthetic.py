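"""Deterministic synthetic taxonomies for testing and demonstration.

Provides the canonical four-node example tree (root A with children B and
C, C parent of D) used throughout the documentation, plus a seeded random
generator of taxonomies and multiparental DAGs so that every module can be
exercised without downloading any real checklist.

The generator aims for structural coverage, not ecological realism: it
makes no attempt to reproduce species-abundance distributions or the
shape statistics of real taxonomic backbones.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ParamError
from .model import (
    PARENT_CHILD,
    TaxonDag,
    TaxonNode,
    Taxonomy,
    build_dag,
    build_taxonomy,
)

#: Linnaean principal ranks, highest first.
DEFAULT_RANK_LADDER = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass
class GenParams:
    """Knobs of the synthetic taxonomy generator.

    ``n_nodes`` nodes are attached one by one to uniformly chosen existing
    nodes with spare child capacity and depth below ``max_depth``; ranks
    follow ``rank_ladder`` by depth (deeper than the ladder = unranked).
    ``hybrid_fraction`` (DAG mode only) is the expected share of non-root
    nodes given a second parent.  The same ``seed`` always yields the
    same output; each call owns its private random stream.
    """

    n_nodes: int = 50
    max_children: int = 6
    max_depth: int = 7
    rank_ladder: tuple[str, ...] = DEFAULT_RANK_LADDER
    hybrid_fraction: float = 0.0
    seed: int = 0
    n_roots: int = 1

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ParamError("n_nodes must be >= 1")
        if not (0 <= self.hybrid_fraction < 1):
            raise ParamError("hybrid_fraction must lie in [0, 1)")
        if self.max_children < 1 or self.max_depth < 1:
            raise ParamError("max_children and max_depth must be >= 1")
        if not (1 <= self.n_roots <= self.n_nodes):
            raise ParamError("n_roots must lie in 1..n_nodes")


def fixture_fig1() -> Taxonomy:
    """The four-node example tree: A is the root, B and C its children
    (B before C), and D the single child of C; B and D are leaves."""
    nodes = [
        TaxonNode("A", name="A", sort_key=0),
        TaxonNode("B", name="B", sort_key=0),
        TaxonNode("C", name="C", sort_key=1),
        TaxonNode("D", name="D", sort_key=0),
    ]
    return build_taxonomy(nodes, [("A", "B"), ("A", "C"), ("C", "D")])


def _grow(p: GenParams, rng: random.Random):
    """Shared tree-growing core; returns nodes and parent->child edges."""
    ids = [f"t{i:04d}" for i in range(1, p.n_nodes + 1)]
    n_roots = min(p.n_roots, p.n_nodes)
    depth: dict[str, int] = {}
    n_children: dict[str, int] = {}
    edges: list[tuple[str, str]] = []
    sort_keys: dict[str, int] = {}

    attachable: list[str] = []
    for i, nid in enumerate(ids):
        if i < n_roots:
            depth[nid] = 0
            sort_keys[nid] = i
        else:
            parent = rng.choice(attachable)
            edges.append((parent, nid))
            depth[nid] = depth[parent] + 1
            sort_keys[nid] = n_children[parent]
            n_children[parent] += 1
            if n_children[parent] >= p.max_children:
                attachable.remove(parent)
        n_children[nid] = 0
        if depth[nid] < p.max_depth:
            attachable.append(nid)
        if not attachable and i + 1 < p.n_nodes:
            raise ParamError(
                "max_children/max_depth leave no room to place all nodes"
            )

    ladder = list(p.rank_ladder)
    nodes = [
        TaxonNode(
            nid,
            name=f"Taxon {nid[1:].lstrip('0') or '0'}",
            rank=ladder[depth[nid]] if depth[nid] < len(ladder) else None,
            sort_key=sort_keys[nid],
        )
        for nid in ids
    ]
    return nodes, edges, depth


def generate_taxonomy(p: GenParams) -> Taxonomy:
    """Generate a random rooted forest of exactly ``p.n_nodes`` nodes.

    Deterministic in ``p.seed``; every output satisfies the forest
    invariants (at most one parent, acyclic, fan-out and depth bounded).
    """
    p.validate()
    rng = random.Random(p.seed)
    nodes, edges, _ = _grow(p, rng)
    return build_taxonomy(nodes, edges)


def generate_dag(p: GenParams) -> TaxonDag:
    """Generate a random multiparental DAG of hybrid-bearing taxa.

    Grows a tree first, then gives a ``hybrid_fraction`` share of non-root
    nodes a second ``parent_child`` edge from a node outside their own
    branch, which preserves acyclicity by construction.  With
    ``hybrid_fraction == 0`` the result is uniparental and convertible to
    a :class:`Taxonomy`.
    """
    p.validate()
    rng = random.Random(p.seed)
    nodes, edges, depth = _grow(p, rng)
    typed = [(a, b, PARENT_CHILD) for a, b in edges]

    if p.hybrid_fraction > 0:
        children: dict[str, list[str]] = {}
        parent: dict[str, str] = {}
        for a, b in edges:
            children.setdefault(a, []).append(b)
            parent[b] = a

        def reachable(nid: str) -> set[str]:
            # descendants over ALL edges so far, hybrid ones included —
            # a second parent drawn from this set would close a cycle
            out = {nid}
            stack = [nid]
            while stack:
                for c in children.get(stack.pop(), []):
                    if c not in out:
                        out.add(c)
                        stack.append(c)
            return out

        for nid in sorted(parent):
            if rng.random() >= p.hybrid_fraction:
                continue
            forbidden = reachable(nid) | {parent[nid]}
            candidates = [x.id for x in nodes if x.id not in forbidden]
            if candidates:
                chosen = rng.choice(candidates)
                typed.append((chosen, nid, PARENT_CHILD))
                children.setdefault(chosen, []).append(nid)
    return build_dag([n for n in nodes], typed)
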