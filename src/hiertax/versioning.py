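"""Change-tracked closure table with whole-tree version stamps.

Taxonomies are living documents: taxa are added, moved between groups and
retired.  Because a closure table stores every (ancestor, descendant)
pair as its own row, history can live *inside* the model: rows are never
edited or deleted, only stamped.  Each row carries the whole-tree version
at which it was created and, once superseded, the version at which it was
invalidated.  Filtering rows by ``created <= v < invalidated`` replays the
exact hierarchy valid at version ``v``, and two snapshots can be diffed.

A reparented taxon does not just change one edge: every pairing of the
moved branch with its former ancestors is invalidated and every pairing
with the new ancestors created.  The diff reports all affected ancestor
pairings, surfacing that a move also changes the substance of the source
and target groups, not only the reparented edge.

Version numbers are monotone integers over the entire tree; timestamps or
authorship can be attached externally as metadata keyed by version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .encodings import closure_pairs
from .errors import (
    InvalidMoveError,
    StructureError,
    UnknownNodeError,
    UnknownVersionError,
)
from .model import PARENT_CHILD, TaxonNode, Taxonomy, build_taxonomy


@dataclass
class VersionedClosureRow:
    ancestor_id: str
    descendant_id: str
    depth: int
    relation_type: str = PARENT_CHILD
    created_version: int = 1
    invalidated_version: int | None = None

    def valid_at(self, version: int) -> bool:
        return self.created_version <= version and (
            self.invalidated_version is None or self.invalidated_version > version
        )


@dataclass
class ChangeOp:
    """One edit: ``add_node``, ``move_node`` or ``delete_node``.

    Payload fields by kind — add_node: ``node`` (a :class:`TaxonNode`),
    ``parent_id`` (None = new root); move_node: ``node_id``,
    ``parent_id``; delete_node: ``node_id``, ``cascade``.
    """

    kind: str
    node: TaxonNode | None = None
    node_id: str | None = None
    parent_id: str | None = None
    cascade: bool = False


@dataclass
class ChangeSet:
    """Difference between two snapshots.

    ``edges_*`` are direct parent→child edges; ``pairs_*`` list every
    affected transitive (ancestor, descendant, depth) pairing.
    """

    nodes_added: list[TaxonNode] = field(default_factory=list)
    nodes_removed: list[str] = field(default_factory=list)
    edges_added: list[tuple[str, str]] = field(default_factory=list)
    edges_removed: list[tuple[str, str]] = field(default_factory=list)
    pairs_added: list[tuple[str, str, int]] = field(default_factory=list)
    pairs_removed: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (
            self.nodes_added
            or self.nodes_removed
            or self.edges_added
            or self.edges_removed
        )

    def invert(self, removed_nodes: list[TaxonNode] | None = None) -> "ChangeSet":
        """The change set mapping the target snapshot back to the source."""
        return ChangeSet(
            nodes_added=list(removed_nodes or []),
            nodes_removed=[n.id for n in self.nodes_added],
            edges_added=list(self.edges_removed),
            edges_removed=list(self.edges_added),
            pairs_added=list(self.pairs_removed),
            pairs_removed=list(self.pairs_added),
        )

    def apply_to(self, tax: Taxonomy) -> Taxonomy:
        """Replay this change set on a snapshot, yielding the target tree."""
        nodes = {n.id: n for n in tax.nodes}
        edges = set(tax.edges())
        edges -= set(self.edges_removed)
        for n in self.nodes_added:
            nodes[n.id] = n
        for nid in self.nodes_removed:
            nodes.pop(nid, None)
        edges |= set(self.edges_added)
        edges = {(p, c) for p, c in edges if p in nodes and c in nodes}
        return build_taxonomy(list(nodes.values()), sorted(edges))


class VersionedClosure:
    """A closure table whose rows carry created/invalidated version stamps."""

    def __init__(self, rows: list[VersionedClosureRow], nodes: dict[str, TaxonNode],
                 current_version: int = 1):
        self.rows = rows
        self._nodes = nodes
        self.current_version = current_version

    # -- queries ---------------------------------------------------------
    def rows_at(self, version: int) -> list[VersionedClosureRow]:
        if not 1 <= version <= self.current_version:
            raise UnknownVersionError(
                f"version {version} outside 1..{self.current_version}"
            )
        return [r for r in self.rows if r.valid_at(version)]

    def closure_at(self, version: int) -> set[tuple[str, str, int]]:
        """The (ancestor, descendant, depth) set valid at ``version``."""
        return {
            (r.ancestor_id, r.descendant_id, r.depth)
            for r in self.rows_at(version)
            if r.relation_type == PARENT_CHILD
        }

    def snapshot(self, version: int) -> Taxonomy:
        """Replay the hierarchy exactly as it stood at ``version``."""
        valid = self.rows_at(version)
        present = {
            r.descendant_id for r in valid if r.depth == 0
        }
        edges = [
            (r.ancestor_id, r.descendant_id)
            for r in valid
            if r.depth == 1 and r.relation_type == PARENT_CHILD
        ]
        nodes = [self._nodes[n] for n in self._nodes if n in present]
        try:
            return build_taxonomy(nodes, sorted(edges))
        except StructureError as e:  # pragma: no cover - append-only safety net
            raise UnknownVersionError(f"corrupt history at version {version}: {e}")

    def to_frame(self) -> pd.DataFrame:
        """All rows (live and invalidated) as a single DataFrame."""
        df = pd.DataFrame(
            [
                {
                    "ancestor_id": r.ancestor_id,
                    "descendant_id": r.descendant_id,
                    "depth": r.depth,
                    "relation_type": r.relation_type,
                    "created_version": r.created_version,
                    "invalidated_version": r.invalidated_version,
                }
                for r in self.rows
            ]
        )
        df["invalidated_version"] = df["invalidated_version"].astype("Int64")
        return df

    # -- editing ---------------------------------------------------------
    def _current(self) -> Taxonomy:
        return self.snapshot(self.current_version)

    def _invalidate(self, pred, version: int) -> None:
        for r in self.rows:
            if r.invalidated_version is None and pred(r):
                r.invalidated_version = version

    def apply_change(self, op: ChangeOp) -> "VersionedClosure":
        """Apply one edit, advancing the whole-tree version by one.

        Existing rows are never rewritten, only stamped with an
        ``invalidated_version``; new rows are stamped with the new version.
        Moves that would put a branch inside itself raise
        :class:`InvalidMoveError`; deletes default to leaf-only unless
        ``cascade`` is set.
        """
        handlers = {
            "add_node": self._apply_add,
            "move_node": self._apply_move,
            "delete_node": self._apply_delete,
        }
        try:
            handler = handlers[op.kind]
        except KeyError:
            raise ValueError(f"unknown change kind: {op.kind!r}") from None
        tax = self._current()
        new_version = self.current_version + 1
        handler(tax, op, new_version)
        self.current_version = new_version
        return self

    def _ancestor_rows_for(
        self, tax: Taxonomy, node_id: str, parent_id: str | None, version: int,
        rel_depth: dict[str, int],
    ) -> list[VersionedClosureRow]:
        """Rows pairing a (re)attached branch with its new strict ancestors."""
        if parent_id is None:
            return []
        chain = tax.ancestors(parent_id) + [parent_id]
        rows = []
        for i, anc in enumerate(chain):
            up = len(chain) - i  # edges from anc down to node_id
            for member, rd in rel_depth.items():
                rows.append(
                    VersionedClosureRow(
                        anc, member, up + rd, PARENT_CHILD, version
                    )
                )
        return rows

    def _apply_add(self, tax: Taxonomy, op: ChangeOp, version: int) -> None:
        node = op.node
        if node is None:
            raise ValueError("add_node needs a TaxonNode payload")
        if node.id in self._nodes and any(
            r.invalidated_version is None and r.descendant_id == node.id
            for r in self.rows
        ):
            raise ValueError(f"node {node.id!r} already present")
        if op.parent_id is not None and op.parent_id not in tax:
            raise UnknownNodeError(op.parent_id)
        self._nodes[node.id] = node
        self.rows.append(
            VersionedClosureRow(node.id, node.id, 0, PARENT_CHILD, version)
        )
        self.rows.extend(
            self._ancestor_rows_for(tax, node.id, op.parent_id, version, {node.id: 0})
        )

    def _apply_move(self, tax: Taxonomy, op: ChangeOp, version: int) -> None:
        nid = op.node_id
        if nid is None or nid not in tax:
            raise UnknownNodeError(str(nid))
        target = op.parent_id
        if target is not None:
            if target not in tax:
                raise UnknownNodeError(target)
            if target == nid or target in tax.descendants(nid):
                raise InvalidMoveError(
                    f"cannot move {nid!r} under its own descendant {target!r}"
                )
        branch = {m: tax.depth(m) - tax.depth(nid) for m in [nid] + tax.descendants(nid)}
        old_ancestors = set(tax.ancestors(nid))
        self._invalidate(
            lambda r: r.ancestor_id in old_ancestors and r.descendant_id in branch,
            version,
        )
        self.rows.extend(
            self._ancestor_rows_for(tax, nid, target, version, branch)
        )

    def _apply_delete(self, tax: Taxonomy, op: ChangeOp, version: int) -> None:
        nid = op.node_id
        if nid is None or nid not in tax:
            raise UnknownNodeError(str(nid))
        members = {nid, *tax.descendants(nid)}
        if len(members) > 1 and not op.cascade:
            raise ValueError(
                f"{nid!r} is not a leaf; pass cascade=True to delete the branch"
            )
        self._invalidate(
            lambda r: r.ancestor_id in members or r.descendant_id in members,
            version,
        )


def init_versioned(tax: Taxonomy) -> VersionedClosure:
    """Start change tracking: the closure of ``tax`` stamped as version 1."""
    rows = [
        VersionedClosureRow(a, d, k, PARENT_CHILD, 1)
        for a, d, k in closure_pairs(tax)
    ]
    return VersionedClosure(rows, {n.id: n for n in tax.nodes}, 1)


def apply_change(vc: VersionedClosure, op: ChangeOp) -> VersionedClosure:
    return vc.apply_change(op)


def snapshot(vc: VersionedClosure, version: int) -> Taxonomy:
    return vc.snapshot(version)


def diff(vc: VersionedClosure, v1: int, v2: int) -> ChangeSet:
    """Change set turning snapshot(v1) into snapshot(v2).

    ``diff(v1, v2)`` and ``diff(v2, v1)`` are mutual inverses and
    ``diff(v, v)`` is empty.  Beyond the direct edges, the set lists every
    transitive ancestor pairing gained or lost, because reclassifying a
    taxon alters the composition of every group above it.
    """
    s1, s2 = vc.snapshot(v1), vc.snapshot(v2)
    n1, n2 = set(s1.node_ids), set(s2.node_ids)
    e1, e2 = set(s1.edges()), set(s2.edges())
    c1, c2 = vc.closure_at(v1), vc.closure_at(v2)
    return ChangeSet(
        nodes_added=[s2.node(n) for n in sorted(n2 - n1)],
        nodes_removed=sorted(n1 - n2),
        edges_added=sorted(e2 - e1),
        edges_removed=sorted(e1 - e2),
        pairs_added=sorted(c2 - c1),
        pairs_removed=sorted(c1 - c2),
    )
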