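"""A uniform hierarchical query suite over every encoding.

The same eight tasks — all parents, direct parent, subtree (with or
without its root), direct children, leaf/root tests, hierarchical sort,
branch aggregation — run against any backend and must return identical
results whether the taxonomy is held canonically in memory or encoded as
an adjacency list, materialized path, nested set, or closure table.

Each backend deliberately uses its model's *native* access path: the
nested-set backend evaluates the literal interval predicates
(``lft < node.lft && rgt > node.rgt`` …), the closure backend filters
(ancestor, descendant, depth) rows, the adjacency backend walks parent
pointers iteratively, and the materialized-path backend does string
prefix matching.  No backend secretly converts to another model.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Callable, Iterable, Mapping

import pandas as pd

from .encodings import (
    ADJACENCY,
    CLOSURE,
    MATERIALIZED_PATH,
    NESTED_SET,
    ModelTableBundle,
)
from .errors import MissingValueError, MultiparentError, UnknownNodeError
from .model import PARENT_CHILD, TaxonDag, Taxonomy

CANONICAL = "canonical"


def _order_index(df: pd.DataFrame) -> dict[str, tuple]:
    """Deterministic sibling sort key per node: sort_key, then row order."""
    out: dict[str, tuple] = {}
    for pos, (_, row) in enumerate(df.iterrows()):
        nid = str(row["node_id"])
        sk = row.get("sort_key")
        has = sk is not None and not pd.isna(sk)
        out[nid] = (not has, int(sk) if has else 0, pos, nid)
    return out


class QueryBackend(ABC):
    """One encoding (or the canonical form) exposed to the query suite."""

    model: str

    @abstractmethod
    def node_ids(self) -> list[str]: ...

    @abstractmethod
    def all_parents(self, node_id: str) -> list[str]:
        """Strict ancestors, root first."""

    @abstractmethod
    def all_direct_parents(self, node_id: str) -> list[str]: ...

    @abstractmethod
    def subtree(self, node_id: str, include_root: bool = False) -> set[str]: ...

    @abstractmethod
    def direct_children(self, node_id: str) -> list[str]: ...

    @abstractmethod
    def hierarchical_sort(self) -> list[str]: ...

    def _check(self, node_id: str) -> None:
        if node_id not in set(self.node_ids()):
            raise UnknownNodeError(node_id)

    def direct_parent(self, node_id: str) -> str | None:
        parents = self.all_direct_parents(node_id)
        if len(parents) > 1:
            raise MultiparentError(
                f"{node_id!r} has {len(parents)} parents; use all_direct_parents"
            )
        return parents[0] if parents else None

    def is_leaf(self, node_id: str) -> bool:
        return not self.subtree(node_id, include_root=False)

    def is_root(self, node_id: str) -> bool:
        return not self.all_parents(node_id)


class TaxonomyBackend(QueryBackend):
    model = CANONICAL

    def __init__(self, tax: Taxonomy):
        self.tax = tax

    def node_ids(self) -> list[str]:
        return self.tax.node_ids

    def all_parents(self, node_id: str) -> list[str]:
        return self.tax.ancestors(node_id)

    def all_direct_parents(self, node_id: str) -> list[str]:
        p = self.tax.parent_of(node_id)
        return [] if p is None else [p]

    def subtree(self, node_id: str, include_root: bool = False) -> set[str]:
        out = set(self.tax.descendants(node_id))
        if include_root:
            out.add(node_id)
        return out

    def direct_children(self, node_id: str) -> list[str]:
        return self.tax.children_of(node_id)

    def hierarchical_sort(self) -> list[str]:
        return self.tax.preorder()


class DagBackend(QueryBackend):
    model = CANONICAL

    def __init__(self, dag: TaxonDag):
        self.dag = dag

    def node_ids(self) -> list[str]:
        return self.dag.node_ids

    def all_parents(self, node_id: str) -> list[str]:
        return self.dag.ancestors(node_id)

    def all_direct_parents(self, node_id: str) -> list[str]:
        return self.dag.parents_of(node_id)

    def subtree(self, node_id: str, include_root: bool = False) -> set[str]:
        self.dag.node(node_id)
        seen = {node_id}
        frontier = [node_id]
        while frontier:
            n = frontier.pop()
            for c in self.dag.children_of(n):
                if c not in seen:
                    seen.add(c)
                    frontier.append(c)
        if not include_root:
            seen.discard(node_id)
        return seen

    def direct_children(self, node_id: str) -> list[str]:
        return self.dag.children_of(node_id)

    def hierarchical_sort(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        stack = [n for n in reversed(self.dag.roots)]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            out.append(n)
            stack.extend(reversed(self.dag.children_of(n)))
        return out


class AdjacencyBackend(QueryBackend):
    """Iterative parent-pointer walks over the adjacency table."""

    model = ADJACENCY

    def __init__(self, bundle: ModelTableBundle):
        df = bundle.table("nodes")
        self._parent: dict[str, str | None] = {}
        children: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            nid = str(row["node_id"])
            p = row.get("parent_id")
            p = None if p is None or pd.isna(p) or p == "" else str(p)
            self._parent[nid] = p
            if p is not None:
                children.setdefault(p, []).append(nid)
        order = _order_index(df)
        self._children = {
            p: sorted(cs, key=order.__getitem__) for p, cs in children.items()
        }
        self._roots = sorted(
            (n for n, p in self._parent.items() if p is None),
            key=order.__getitem__,
        )

    def node_ids(self) -> list[str]:
        return list(self._parent)

    def all_parents(self, node_id: str) -> list[str]:
        self._check(node_id)
        chain: list[str] = []
        cur = self._parent[node_id]
        while cur is not None:
            chain.append(cur)
            cur = self._parent[cur]
        chain.reverse()
        return chain

    def all_direct_parents(self, node_id: str) -> list[str]:
        self._check(node_id)
        p = self._parent[node_id]
        return [] if p is None else [p]

    def subtree(self, node_id: str, include_root: bool = False) -> set[str]:
        self._check(node_id)
        out: set[str] = {node_id} if include_root else set()
        frontier = [node_id]
        while frontier:
            n = frontier.pop()
            for c in self._children.get(n, []):
                out.add(c)
                frontier.append(c)
        return out

    def direct_children(self, node_id: str) -> list[str]:
        self._check(node_id)
        return list(self._children.get(node_id, []))

    def hierarchical_sort(self) -> list[str]:
        out: list[str] = []
        stack = list(reversed(self._roots))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self._children.get(n, [])))
        return out


class MaterializedPathBackend(QueryBackend):
    """String prefix matching over stored ancestor paths."""

    model = MATERIALIZED_PATH

    def __init__(self, bundle: ModelTableBundle):
        df = bundle.table("nodes")
        self.delim = bundle.delimiter
        self._path: dict[str, str] = {}
        for _, row in df.iterrows():
            p = row.get("path")
            self._path[str(row["node_id"])] = (
                "" if p is None or pd.isna(p) else str(p)
            )
        self._order = _order_index(df)

    def node_ids(self) -> list[str]:
        return list(self._path)

    def _full(self, node_id: str) -> str:
        path = self._path[node_id]
        return f"{path}{self.delim}{node_id}" if path else node_id

    def all_parents(self, node_id: str) -> list[str]:
        self._check(node_id)
        path = self._path[node_id]
        return path.split(self.delim) if path else []

    def all_direct_parents(self, node_id: str) -> list[str]:
        return self.all_parents(node_id)[-1:]

    def subtree(self, node_id: str, include_root: bool = False) -> set[str]:
        self._check(node_id)
        prefix = self._full(node_id)
        out = {
            n
            for n, p in self._path.items()
            if p == prefix or p.startswith(prefix + self.delim)
        }
        if include_root:
            out.add(node_id)
        return out

    def direct_children(self, node_id: str) -> list[str]:
        self._check(node_id)
        prefix = self._full(node_id)
        return sorted(
            (n for n, p in self._path.items() if p == prefix),
            key=self._order.__getitem__,
        )

    def hierarchical_sort(self) -> list[str]:
        out: list[str] = []
        roots = sorted(
            (n for n, p in self._path.items() if p == ""),
            key=self._order.__getitem__,
        )
        stack = list(reversed(roots))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.direct_children(n)))
        return out


class NestedSetBackend(QueryBackend):
    """Literal lft/rgt interval predicates, as filterable in a spreadsheet."""

    model = NESTED_SET

    def __init__(self, bundle: ModelTableBundle):
        self.df = bundle.table("nodes")
        self._by_id = self.df.set_index(self.df["node_id"].astype(str))

    def node_ids(self) -> list[str]:
        return self.df["node_id"].astype(str).tolist()

    def _row(self, node_id: str):
        try:
            return self._by_id.loc[node_id]
        except KeyError:
            raise UnknownNodeError(node_id) from None

    def all_parents(self, node_id: str) -> list[str]:
        node = self._row(node_id)
        hits = self.df[(self.df["lft"] < node["lft"]) & (self.df["rgt"] > node["rgt"])]
        return hits.sort_values("lft")["node_id"].astype(str).tolist()

    def all_direct_parents(self, node_id: str) -> list[str]:
        node = self._row(node_id)
        hits = self.df[
            (self.df["lft"] < node["lft"])
            & (self.df["rgt"] > node["rgt"])
            & (self.df["depth"] == node["depth"] - 1)
        ]
        return hits["node_id"].astype(str).tolist()

    def subtree(self, node_id: str, include_root: bool = False) -> set[str]:
        node = self._row(node_id)
        if include_root:
            hits = self.df[
                (self.df["lft"] >= node["lft"]) & (self.df["rgt"] <= node["rgt"])
            ]
        else:
            hits = self.df[
                (self.df["lft"] > node["lft"]) & (self.df["rgt"] < node["rgt"])
            ]
        return set(hits["node_id"].astype(str))

    def direct_children(self, node_id: str) -> list[str]:
        node = self._row(node_id)
        hits = self.df[
            (self.df["lft"] > node["lft"])
            & (self.df["rgt"] < node["rgt"])
            & (self.df["depth"] == node["depth"] + 1)
        ]
        return hits.sort_values("lft")["node_id"].astype(str).tolist()

    def is_leaf(self, node_id: str) -> bool:
        node = self._row(node_id)
        return bool(node["lft"] == node["rgt"] - 1)

    def is_root(self, node_id: str) -> bool:
        node = self._row(node_id)
        return bool(node["depth"] == 0)

    def hierarchical_sort(self) -> list[str]:
        # ascending lft is exactly hierarchical order, siblings included
        return self.df.sort_values("lft")["node_id"].astype(str).tolist()


class ClosureBackend(QueryBackend):
    """Row filters on the (ancestor, descendant, depth) hierarchy table."""

    model = CLOSURE

    def __init__(self, bundle: ModelTableBundle):
        hier = bundle.table("hierarchy")
        if "relation_type" in hier.columns:
            hier = hier[
                hier["relation_type"].fillna(PARENT_CHILD).astype(str)
                == PARENT_CHILD
            ]
        self.hier = hier.astype({"depth": int})
        self._order = _order_index(bundle.table("nodes"))
        self._ids = (
            bundle.table("nodes")["node_id"].astype(str).tolist()
        )

    def node_ids(self) -> list[str]:
        return list(self._ids)

    def all_parents(self, node_id: str) -> list[str]:
        self._check(node_id)
        hits = self.hier[
            (self.hier["descendant_id"].astype(str) == node_id)
            & (self.hier["depth"] > 0)
        ]
        # sort by decreasing depth = root first; ids break DAG ties
        ordered = sorted(
            ((int(r["depth"]), str(r["ancestor_id"])) for _, r in hits.iterrows()),
            key=lambda t: (-t[0], t[1]),
        )
        return [a for _, a in ordered]

    def all_direct_parents(self, node_id: str) -> list[str]:
        self._check(node_id)
        hits = self.hier[
            (self.hier["descendant_id"].astype(str) == node_id)
            & (self.hier["depth"] == 1)
        ]
        return sorted(hits["ancestor_id"].astype(str))

    def subtree(self, node_id: str, include_root: bool = False) -> set[str]:
        self._check(node_id)
        mask = self.hier["ancestor_id"].astype(str) == node_id
        if not include_root:
            mask &= self.hier["depth"] > 0
        return set(self.hier[mask]["descendant_id"].astype(str))

    def direct_children(self, node_id: str) -> list[str]:
        self._check(node_id)
        hits = self.hier[
            (self.hier["ancestor_id"].astype(str) == node_id)
            & (self.hier["depth"] == 1)
        ]
        return sorted(hits["descendant_id"].astype(str), key=self._order.__getitem__)

    def is_leaf(self, node_id: str) -> bool:
        self._check(node_id)
        return not (
            (self.hier["ancestor_id"].astype(str) == node_id)
            & (self.hier["depth"] > 0)
        ).any()

    def is_root(self, node_id: str) -> bool:
        self._check(node_id)
        return not (
            (self.hier["descendant_id"].astype(str) == node_id)
            & (self.hier["depth"] > 0)
        ).any()

    def hierarchical_sort(self) -> list[str]:
        roots = sorted(
            (n for n in self._ids if self.is_root(n)), key=self._order.__getitem__
        )
        out: list[str] = []
        seen: set[str] = set()
        stack = list(reversed(roots))
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            out.append(n)
            stack.extend(reversed(self.direct_children(n)))
        return out


_BACKENDS: dict[str, type[QueryBackend]] = {
    ADJACENCY: AdjacencyBackend,
    MATERIALIZED_PATH: MaterializedPathBackend,
    NESTED_SET: NestedSetBackend,
    CLOSURE: ClosureBackend,
}


def make_backend(
    obj: Taxonomy | TaxonDag | ModelTableBundle | QueryBackend,
) -> QueryBackend:
    """Wrap a taxonomy, DAG, or encoded bundle as a query backend."""
    if isinstance(obj, QueryBackend):
        return obj
    if isinstance(obj, Taxonomy):
        return TaxonomyBackend(obj)
    if isinstance(obj, TaxonDag):
        return DagBackend(obj)
    if isinstance(obj, ModelTableBundle):
        return _BACKENDS[obj.model](obj)
    raise TypeError(f"cannot build a query backend from {type(obj).__name__}")


# -- functional façade -------------------------------------------------------


def all_parents(backend, node_id: str) -> list[str]:
    """All strict ancestors of a node, ordered root → immediate parent."""
    return make_backend(backend).all_parents(node_id)


def direct_parent(backend, node_id: str) -> str | None:
    """The unique parent, or ``None`` for roots; multiparental nodes raise."""
    return make_backend(backend).direct_parent(node_id)


def all_direct_parents(backend, node_id: str) -> list[str]:
    return make_backend(backend).all_direct_parents(node_id)


def subtree(backend, node_id: str, include_root: bool = False) -> set[str]:
    """All descendants of a node; the branch root itself only on request."""
    return make_backend(backend).subtree(node_id, include_root=include_root)


def direct_children(backend, node_id: str) -> list[str]:
    return make_backend(backend).direct_children(node_id)


def is_leaf(backend, node_id: str) -> bool:
    return make_backend(backend).is_leaf(node_id)


def is_root(backend, node_id: str) -> bool:
    return make_backend(backend).is_root(node_id)


def hierarchical_sort(backend) -> list[str]:
    """Pre-order listing: parents precede descendants, siblings in order."""
    return make_backend(backend).hierarchical_sort()


def aggregate_branch(
    backend,
    node_id: str,
    values: Mapping[str, float],
    combine: Callable[[Iterable[float]], float] = sum,
) -> float:
    """Fold ``values`` over a branch (the node plus all its descendants).

    Typical use: species-level occurrence counts aggregated to include
    subspecies.  ``combine`` receives the member values in hierarchical
    order; missing members raise :class:`MissingValueError`.
    """
    be = make_backend(backend)
    members = be.subtree(node_id, include_root=True)
    missing = sorted(m for m in members if m not in values)
    if missing:
        raise MissingValueError(missing)
    ordered = [n for n in be.hierarchical_sort() if n in members]
    return combine(values[m] for m in ordered)
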