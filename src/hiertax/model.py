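"""Canonical in-memory representation of taxon hierarchies.

A taxonomy is a rooted forest: every node has at most one parent
(a *uniparental* directed acyclic graph) and siblings carry a total order.
Biological information — names, ranks — is deliberately treated as node
metadata, never as identity: node ids are opaque strings.

Hybrid taxa need two parents, which no tree can hold; :class:`TaxonDag`
relaxes the uniparental constraint and additionally allows typed,
non-hierarchical relationships (``part_of``, ``congruent``, ``overlap``)
alongside the default ``parent_child``.  Only ``parent_child`` edges
participate in ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import MultiparentError, StructureError, UnknownNodeError

PARENT_CHILD = "parent_child"
#: Relation types with reserved meaning; the vocabulary is open beyond these.
RESERVED_RELATIONS = (PARENT_CHILD, "part_of", "congruent", "overlap")


@dataclass(frozen=True)
class TaxonNode:
    """A node of the hierarchy: opaque id plus biological metadata.

    Parameters
    ----------
    id:
        Unique opaque identifier within one taxonomy.
    name:
        Display name (e.g. a scientific name); not used for identity.
    rank:
        Controlled rank label such as ``"family"``; optional metadata.
    sort_key:
        Integer sibling-order key.  Lower keys sort first; nodes without a
        key fall back to insertion order, then lexicographic id.
    """

    id: str
    name: str | None = None
    rank: str | None = None
    sort_key: int | None = None


@dataclass(frozen=True)
class Violation:
    code: str
    node_ids: tuple[str, ...]
    message: str


@dataclass
class ValidationReport:
    """Outcome of structural edge validation; ``ok`` iff no violations."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}


def validate_edges(
    edges: Iterable[tuple[str, str]],
    node_ids: Iterable[str] | None = None,
) -> ValidationReport:
    """Check a parent→child edge list for structural violations.

    Reports (never raises) three violation codes:

    * ``CYCLE`` — a directed cycle exists; the node set of all cycle
      participants is reported once.
    * ``MULTIPARENT`` — a child appears with more than one distinct parent.
    * ``DANGLING`` — an edge references an id outside ``node_ids``
      (only checked when ``node_ids`` is given).

    The result is independent of edge order: permuting the input yields the
    same violation set.
    """
    edges = [(str(p), str(c)) for p, c in edges]
    report = ValidationReport()

    if node_ids is not None:
        declared = set(node_ids)
        dangling = sorted(
            {x for e in edges for x in e if x not in declared}
        )
        if dangling:
            report.violations.append(
                Violation(
                    "DANGLING",
                    tuple(dangling),
                    f"edges reference undeclared ids: {', '.join(dangling)}",
                )
            )

    parents: dict[str, set[str]] = {}
    for p, c in edges:
        parents.setdefault(c, set()).add(p)
    for child in sorted(parents):
        if len(parents[child]) > 1:
            report.violations.append(
                Violation(
                    "MULTIPARENT",
                    (child,),
                    f"node {child!r} has {len(parents[child])} parents",
                )
            )

    cyclic = _cycle_participants(edges)
    if cyclic:
        report.violations.append(
            Violation(
                "CYCLE",
                tuple(sorted(cyclic)),
                f"directed cycle involving: {', '.join(sorted(cyclic))}",
            )
        )
    return report


def _cycle_participants(edges: Sequence[tuple[str, str]]) -> set[str]:
    """Nodes lying on at least one directed cycle.

    Iteratively strips sources, then sinks; whatever survives both passes
    sits on (or between) cycles.  Exact enough for reporting and O(V + E).
    """
    nodes = {x for e in edges for x in e}
    out: dict[str, set[str]] = {n: set() for n in nodes}
    inn: dict[str, set[str]] = {n: set() for n in nodes}
    for p, c in edges:
        out[p].add(c)
        inn[c].add(p)
    alive = set(nodes)
    for degree_of, other in ((inn, out), (out, inn)):
        queue = [n for n in alive if not (degree_of[n] & alive)]
        while queue:
            n = queue.pop()
            alive.discard(n)
            for m in other[n]:
                if m in alive and not (degree_of[m] & alive):
                    queue.append(m)
    return alive


def _sibling_sorted(
    children: Sequence[str], nodes: Mapping[str, TaxonNode]
) -> list[str]:
    """Order siblings: sort_key first, then given order, then id."""
    indexed = list(enumerate(children))
    indexed.sort(
        key=lambda t: (
            nodes[t[1]].sort_key is None,
            nodes[t[1]].sort_key if nodes[t[1]].sort_key is not None else 0,
            t[0],
            t[1],
        )
    )
    return [c for _, c in indexed]


class Taxonomy:
    """A rooted forest of :class:`TaxonNode` with ordered siblings.

    Construct via :func:`build_taxonomy`; the constructor assumes the
    arguments already satisfy the forest invariants.
    """

    def __init__(
        self,
        nodes: Mapping[str, TaxonNode],
        parent: Mapping[str, str],
        children: Mapping[str, list[str]],
        root_order: Sequence[str],
    ):
        self._nodes = dict(nodes)
        self._parent = dict(parent)
        self._children = {k: list(v) for k, v in children.items()}
        self._roots = list(root_order)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __iter__(self) -> Iterator[str]:
        return iter(self.preorder())

    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def node(self, node_id: str) -> TaxonNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    @property
    def nodes(self) -> list[TaxonNode]:
        return list(self._nodes.values())

    @property
    def roots(self) -> list[str]:
        return list(self._roots)

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if not self._children.get(n)]

    def parent_of(self, node_id: str) -> str | None:
        self.node(node_id)
        return self._parent.get(node_id)

    def children_of(self, node_id: str) -> list[str]:
        self.node(node_id)
        return list(self._children.get(node_id, []))

    # -- traversal -------------------------------------------------------
    def preorder(self) -> list[str]:
        """Depth-first pre-order over all components, siblings in order."""
        out: list[str] = []
        stack = list(reversed(self._roots))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self._children.get(n, [])))
        return out

    def ancestors(self, node_id: str) -> list[str]:
        """Strict ancestors, ordered root first."""
        self.node(node_id)
        chain: list[str] = []
        cur = self._parent.get(node_id)
        while cur is not None:
            chain.append(cur)
            cur = self._parent.get(cur)
        chain.reverse()
        return chain

    def descendants(self, node_id: str) -> list[str]:
        """Strict descendants in pre-order."""
        self.node(node_id)
        out: list[str] = []
        stack = list(reversed(self._children.get(node_id, [])))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self._children.get(n, [])))
        return out

    def depth(self, node_id: str) -> int:
        return len(self.ancestors(node_id))

    def edges(self) -> list[tuple[str, str]]:
        """Parent→child edges in pre-order of the child."""
        return [
            (self._parent[n], n) for n in self.preorder() if n in self._parent
        ]

    # -- comparison ------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and self._parent == other._parent
            and self.preorder() == other.preorder()
        )

    def topology_equal(self, other: "Taxonomy", *, ordered: bool = True) -> bool:
        """Same ids and edges; with ``ordered`` also the same sibling order."""
        if set(self._nodes) != set(other._nodes):
            return False
        if self._parent != other._parent:
            return False
        return (not ordered) or self.preorder() == other.preorder()

    def __repr__(self) -> str:
        return f"<Taxonomy n={len(self)} roots={self._roots!r}>"


class TaxonDag:
    """A multiparental DAG with typed edges.

    Ancestry (``parents_of``, ``ancestors`` …) is computed over
    ``parent_child`` edges only; other relation types are stored verbatim
    and ignored by hierarchy traversal.
    """

    def __init__(
        self,
        nodes: Mapping[str, TaxonNode],
        edges: Sequence[tuple[str, str, str]],
    ):
        self._nodes = dict(nodes)
        self._edges = [tuple(e) for e in edges]
        self._parents: dict[str, list[str]] = {n: [] for n in self._nodes}
        self._children: dict[str, list[str]] = {n: [] for n in self._nodes}
        for p, c, rel in self._edges:
            if rel == PARENT_CHILD:
                self._parents[c].append(p)
                self._children[p].append(c)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def node(self, node_id: str) -> TaxonNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    @property
    def nodes(self) -> list[TaxonNode]:
        return list(self._nodes.values())

    @property
    def typed_edges(self) -> list[tuple[str, str, str]]:
        return list(self._edges)

    def hierarchy_edges(self) -> list[tuple[str, str]]:
        return [(p, c) for p, c, rel in self._edges if rel == PARENT_CHILD]

    def parents_of(self, node_id: str) -> list[str]:
        self.node(node_id)
        return list(self._parents[node_id])

    def children_of(self, node_id: str) -> list[str]:
        self.node(node_id)
        return list(self._children[node_id])

    @property
    def roots(self) -> list[str]:
        return [n for n in self._nodes if not self._parents[n]]

    def ancestors(self, node_id: str) -> list[str]:
        """All strict ancestors in a deterministic topological order.

        On a multiparental DAG there is no single root→node chain; ancestors
        are returned sorted by decreasing distance-to-node, ties by id, which
        coincides with the root-first chain on trees.
        """
        dist = self.ancestor_depths(node_id)
        dist.pop(node_id, None)
        return sorted(dist, key=lambda a: (-dist[a], a))

    def ancestor_depths(self, node_id: str) -> dict[str, int]:
        """Minimum path length (edges) from each ancestor-or-self down to the node."""
        self.node(node_id)
        dist = {node_id: 0}
        frontier = [node_id]
        while frontier:
            nxt: list[str] = []
            for n in frontier:
                for p in self._parents[n]:
                    if p not in dist:
                        dist[p] = dist[n] + 1
                        nxt.append(p)
                    else:
                        dist[p] = min(dist[p], dist[n] + 1)
            frontier = nxt
        return dist

    def is_uniparental(self) -> bool:
        return all(len(ps) <= 1 for ps in self._parents.values())

    def to_taxonomy(self) -> Taxonomy:
        """View a uniparental, purely parent_child DAG as a Taxonomy."""
        multi = [n for n, ps in self._parents.items() if len(ps) > 1]
        if multi:
            raise MultiparentError(
                f"nodes with multiple parents: {', '.join(sorted(multi))}"
            )
        return build_taxonomy(self.nodes, self.hierarchy_edges())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonDag):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __repr__(self) -> str:
        return f"<TaxonDag n={len(self)} edges={len(self._edges)}>"


def _as_node_map(nodes: Iterable[TaxonNode | str]) -> dict[str, TaxonNode]:
    out: dict[str, TaxonNode] = {}
    for n in nodes:
        node = TaxonNode(n) if isinstance(n, str) else n
        out[node.id] = node
    return out


def build_taxonomy(
    nodes: Iterable[TaxonNode | str],
    edges: Iterable[tuple[str, str]],
) -> Taxonomy:
    """Assemble a validated :class:`Taxonomy` from nodes and parent→child edges.

    Raises :class:`StructureError` (wrapping the full report) on cycles,
    multiple parents, or edges over undeclared ids.  Sibling order is taken
    from ``sort_key`` where present, with input edge order breaking ties.
    Bare strings are accepted in ``nodes`` as metadata-free nodes.
    """
    node_map = _as_node_map(nodes)
    edge_list = [(str(p), str(c)) for p, c in edges]
    report = validate_edges(edge_list, node_map)
    if not report.ok:
        raise StructureError(report)

    parent: dict[str, str] = {}
    children: dict[str, list[str]] = {}
    for p, c in edge_list:
        parent[c] = p
        children.setdefault(p, []).append(c)
    children = {
        p: _sibling_sorted(cs, node_map) for p, cs in children.items()
    }
    roots = _sibling_sorted(
        [n for n in node_map if n not in parent], node_map
    )
    return Taxonomy(node_map, parent, children, roots)


def build_dag(
    nodes: Iterable[TaxonNode | str],
    typed_edges: Iterable[tuple[str, str] | tuple[str, str, str]],
) -> TaxonDag:
    """Assemble a validated :class:`TaxonDag` from typed edges.

    Edges default to ``parent_child``.  Cycles are forbidden over
    ``parent_child`` edges only; other relation types never participate in
    ancestry, so cycles among them are tolerated.
    """
    node_map = _as_node_map(nodes)
    edges: list[tuple[str, str, str]] = []
    for e in typed_edges:
        if len(e) == 2:
            p, c = e
            rel = PARENT_CHILD
        else:
            p, c, rel = e
        edges.append((str(p), str(c), str(rel)))

    pc_edges = [(p, c) for p, c, rel in edges if rel == PARENT_CHILD]
    report = validate_edges(pc_edges, node_map)
    dangling = sorted(
        {x for p, c, _ in edges for x in (p, c) if x not in node_map}
    )
    blocking = [
        v for v in report.violations if v.code in ("CYCLE", "DANGLING")
    ]
    if dangling and "DANGLING" not in {v.code for v in blocking}:
        blocking.append(
            Violation("DANGLING", tuple(dangling), "typed edges reference undeclared ids")
        )
    if blocking:
        raise StructureError(ValidationReport(blocking))
    return TaxonDag(node_map, edges)
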