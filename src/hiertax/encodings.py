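"""The four relational encodings of a taxon hierarchy and their inverses.

Each encoder turns the canonical :class:`~hiertax.model.Taxonomy` (or, for
the closure table, also a :class:`~hiertax.model.TaxonDag`) into a
:class:`ModelTableBundle` of pandas DataFrames shaped exactly like the
corresponding relational tables:

``adjacency_list``
    one table, each node stores its parent's id;
``materialized_path``
    one table, each node stores the delimiter-joined ids of its ancestors
    (highest first, self excluded);
``nested_set``
    one table, each node stores the (lft, rgt) interval from a double-visit
    depth-first traversal, plus a redundant ``depth`` that speeds up
    direct-parent/direct-child queries;
``closure_table``
    two tables — the hierarchy is kept separate from the node objects — with
    one row per (ancestor, descendant) pair including a depth-0 self row.

Only the closure table can hold multiparental (hybrid) taxa; the three
uniparental encoders raise :class:`~hiertax.errors.MultiparentError` when
handed a DAG with a twice-parented node.

Node metadata (name, rank, sort_key) rides along in extra columns by
default so that ``decode(encode_M(t)) == t`` exactly, including sibling
order, for every model M.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConsistencyError, DelimiterError, StructureError
from .model import (
    PARENT_CHILD,
    TaxonDag,
    TaxonNode,
    Taxonomy,
    build_dag,
    build_taxonomy,
    validate_edges,
)

ADJACENCY = "adjacency_list"
MATERIALIZED_PATH = "materialized_path"
NESTED_SET = "nested_set"
CLOSURE = "closure_table"
MODELS = (ADJACENCY, MATERIALIZED_PATH, NESTED_SET, CLOSURE)

DEFAULT_DELIMITER = "|"

_META_COLS = ("name", "rank", "sort_key")


@dataclass
class ModelTableBundle:
    """Named tables realizing one relational model.

    ``closure_table`` bundles hold exactly two tables (``nodes`` +
    ``hierarchy``); every other model holds exactly one (``nodes``).
    ``delimiter`` is only meaningful for materialized paths.
    """

    model: str
    tables: dict[str, pd.DataFrame]
    delimiter: str = DEFAULT_DELIMITER

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model: {self.model!r}")
        expected = 2 if self.model == CLOSURE else 1
        if len(self.tables) != expected:
            raise ValueError(
                f"{self.model} bundle must have {expected} table(s), "
                f"got {len(self.tables)}"
            )

    @property
    def table_count(self) -> int:
        return len(self.tables)

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _meta_frame(nodes: list[TaxonNode]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "name": [n.name for n in nodes],
            "rank": [n.rank for n in nodes],
            "sort_key": [n.sort_key for n in nodes],
        }
    )
    df["sort_key"] = df["sort_key"].astype("Int64")
    return df


def _nodes_in_order(tax: Taxonomy) -> list[TaxonNode]:
    return [tax.node(i) for i in tax.preorder()]


def _require_taxonomy(obj: Taxonomy | TaxonDag) -> Taxonomy:
    if isinstance(obj, Taxonomy):
        return obj
    return obj.to_taxonomy()  # raises MultiparentError on hybrids


# ---------------------------------------------------------------------------
# encoders


def encode_adjacency(
    tax: Taxonomy | TaxonDag, *, include_metadata: bool = True
) -> ModelTableBundle:
    """Adjacency list: one row per node carrying its parent's id.

    Rows are written in hierarchical (pre-)order; roots carry an empty
    ``parent_id``.
    """
    tax = _require_taxonomy(tax)
    nodes = _nodes_in_order(tax)
    df = pd.DataFrame(
        {
            "node_id": [n.id for n in nodes],
            "parent_id": [tax.parent_of(n.id) or "" for n in nodes],
        }
    )
    if include_metadata:
        df = pd.concat([df, _meta_frame(nodes)], axis=1)
    return ModelTableBundle(ADJACENCY, {"nodes": df})


def encode_materialized_path(
    tax: Taxonomy | TaxonDag,
    delimiter: str = DEFAULT_DELIMITER,
    *,
    include_metadata: bool = True,
) -> ModelTableBundle:
    """Materialized path: each node stores its full ancestor id path.

    The path lists ancestor ids highest→lowest joined by ``delimiter``,
    excluding the node itself; roots store the empty string.  Raises
    :class:`DelimiterError` if any node id contains the delimiter.
    """
    tax = _require_taxonomy(tax)
    offenders = [i for i in tax.node_ids if delimiter in i]
    if offenders:
        raise DelimiterError(
            f"node ids contain delimiter {delimiter!r}: {', '.join(sorted(offenders))}"
        )
    nodes = _nodes_in_order(tax)
    df = pd.DataFrame(
        {
            "node_id": [n.id for n in nodes],
            "path": [delimiter.join(tax.ancestors(n.id)) for n in nodes],
        }
    )
    if include_metadata:
        df = pd.concat([df, _meta_frame(nodes)], axis=1)
    return ModelTableBundle(MATERIALIZED_PATH, {"nodes": df}, delimiter=delimiter)


def encode_nested_set(
    tax: Taxonomy | TaxonDag, *, include_metadata: bool = True
) -> ModelTableBundle:
    """Nested set: double-visit DFS numbering of the whole forest.

    ``lft`` is assigned when a node is entered, ``rgt`` when it is left, so
    over n nodes the values form a permutation of 1..2n and every
    descendant interval nests strictly inside its ancestor's.  Numbering
    starts at 1 and runs through the forest's components consecutively in
    root order, so the permutation invariant holds forest-wide.  The
    redundant ``depth`` column (root = 0) is stored explicitly.
    """
    tax = _require_taxonomy(tax)
    lft: dict[str, int] = {}
    rgt: dict[str, int] = {}
    counter = 0
    for root in tax.roots:
        # explicit stack: (node, entered?)
        stack: list[tuple[str, bool]] = [(root, False)]
        while stack:
            node, entered = stack.pop()
            if entered:
                counter += 1
                rgt[node] = counter
            else:
                counter += 1
                lft[node] = counter
                stack.append((node, True))
                for child in reversed(tax.children_of(node)):
                    stack.append((child, False))
    nodes = _nodes_in_order(tax)
    df = pd.DataFrame(
        {
            "node_id": [n.id for n in nodes],
            "lft": [lft[n.id] for n in nodes],
            "rgt": [rgt[n.id] for n in nodes],
            "depth": [tax.depth(n.id) for n in nodes],
        }
    )
    if include_metadata:
        df = pd.concat([df, _meta_frame(nodes)], axis=1)
    return ModelTableBundle(NESTED_SET, {"nodes": df})


def closure_pairs(obj: Taxonomy | TaxonDag) -> list[tuple[str, str, int]]:
    """All (ancestor, descendant, depth) pairs including depth-0 self rows.

    On trees the depth is the unique path length; on multiparental DAGs it
    is the minimum path length over ``parent_child`` edges, keeping the
    table a set (one row per pair).
    """
    rows: list[tuple[str, str, int]] = []
    if isinstance(obj, Taxonomy):
        for n in obj.preorder():
            chain = obj.ancestors(n) + [n]
            d = len(chain) - 1
            for i, a in enumerate(chain):
                rows.append((a, n, d - i))
    else:
        for n in obj.node_ids:
            for a, d in sorted(obj.ancestor_depths(n).items()):
                rows.append((a, n, d))
    return rows


def encode_closure(
    obj: Taxonomy | TaxonDag, *, include_metadata: bool = True
) -> ModelTableBundle:
    """Closure table: hierarchy separated from node objects (two tables).

    The ``hierarchy`` table holds one row per reachable (ancestor,
    descendant) pair over ``parent_child`` edges, including a (x, x, 0)
    self row per node; for a tree its row count is Σ over nodes of
    (depth + 1).  Non-hierarchical typed edges of a DAG (``part_of``,
    ``congruent``, ``overlap``…) are stored as additional rows tagged with
    their ``relation_type`` at depth 1; ancestry rows are ``parent_child``.
    This is the only one of the four models that can hold multiparental
    (hybrid) structures.
    """
    if isinstance(obj, TaxonDag):
        node_list = [obj.node(i) for i in sorted(obj.node_ids)]
        extra = [
            (p, c, 1, rel)
            for p, c, rel in obj.typed_edges
            if rel != PARENT_CHILD
        ]
    else:
        node_list = _nodes_in_order(obj)
        extra = []

    nodes_df = pd.DataFrame(
        {
            "node_id": [n.id for n in node_list],
            "name": [n.name for n in node_list],
            "rank": [n.rank for n in node_list],
        }
    )
    if include_metadata:
        nodes_df["sort_key"] = pd.array(
            [n.sort_key for n in node_list], dtype="Int64"
        )

    pairs = closure_pairs(obj)
    hier = pd.DataFrame(
        {
            "ancestor_id": [a for a, _, _ in pairs],
            "descendant_id": [d for _, d, _ in pairs],
            "depth": [k for _, _, k in pairs],
        }
    )
    if extra:
        hier["relation_type"] = PARENT_CHILD
        hier = pd.concat(
            [
                hier,
                pd.DataFrame(
                    extra,
                    columns=["ancestor_id", "descendant_id", "depth", "relation_type"],
                ),
            ],
            ignore_index=True,
        )
    return ModelTableBundle(CLOSURE, {"nodes": nodes_df, "hierarchy": hier})


def encode(obj: Taxonomy | TaxonDag, model: str, **kwargs) -> ModelTableBundle:
    """Dispatch to the encoder for ``model``."""
    encoders = {
        ADJACENCY: encode_adjacency,
        MATERIALIZED_PATH: encode_materialized_path,
        NESTED_SET: encode_nested_set,
        CLOSURE: encode_closure,
    }
    try:
        enc = encoders[model]
    except KeyError:
        raise ValueError(f"unknown model: {model!r}") from None
    return enc(obj, **kwargs)


# ---------------------------------------------------------------------------
# decoders


def _cell(row, col):
    if col not in row or pd.isna(row[col]):
        return None
    return row[col]


def _node_from_row(row) -> TaxonNode:
    sk = _cell(row, "sort_key")
    return TaxonNode(
        id=str(row["node_id"]),
        name=None if (v := _cell(row, "name")) is None else str(v),
        rank=None if (v := _cell(row, "rank")) is None else str(v),
        sort_key=None if sk is None else int(sk),
    )


def decode(bundle: ModelTableBundle) -> Taxonomy | TaxonDag:
    """Reconstruct the canonical form from any model bundle.

    Each decoder validates its model's invariants first and raises
    :class:`ConsistencyError` on malformed tables (improper nested-set
    intervals, closure tables missing self rows or transitive pairs,
    orphan path prefixes, adjacency cycles).  A closure bundle carrying
    multiparental rows decodes to a :class:`TaxonDag`; everything else
    decodes to a :class:`Taxonomy`.
    """
    decoders = {
        ADJACENCY: _decode_adjacency,
        MATERIALIZED_PATH: _decode_materialized_path,
        NESTED_SET: _decode_nested_set,
        CLOSURE: _decode_closure,
    }
    return decoders[bundle.model](bundle)


def _decode_adjacency(bundle: ModelTableBundle) -> Taxonomy:
    df = bundle.table("nodes")
    nodes = [_node_from_row(r) for _, r in df.iterrows()]
    edges = [
        (str(r["parent_id"]), str(r["node_id"]))
        for _, r in df.iterrows()
        if _cell(r, "parent_id") not in (None, "")
    ]
    try:
        return build_taxonomy(nodes, edges)
    except StructureError as e:
        raise ConsistencyError(f"invalid adjacency table: {e}") from e


def _decode_materialized_path(bundle: ModelTableBundle) -> Taxonomy:
    df = bundle.table("nodes")
    delim = bundle.delimiter
    nodes = [_node_from_row(r) for _, r in df.iterrows()]
    paths: dict[str, str] = {
        str(r["node_id"]): ("" if _cell(r, "path") is None else str(r["path"]))
        for _, r in df.iterrows()
    }
    edges: list[tuple[str, str]] = []
    for nid, path in paths.items():
        if not path:
            continue
        tokens = path.split(delim)
        parent = tokens[-1]
        parent_prefix = delim.join(tokens[:-1])
        if parent not in paths or paths[parent] != parent_prefix:
            raise ConsistencyError(
                f"path of {nid!r} ({path!r}) has no consistent parent row"
            )
        edges.append((parent, nid))
    try:
        return build_taxonomy(nodes, edges)
    except StructureError as e:
        raise ConsistencyError(f"invalid materialized-path table: {e}") from e


def _decode_nested_set(bundle: ModelTableBundle) -> Taxonomy:
    df = bundle.table("nodes").sort_values("lft")
    n = len(df)
    values = sorted(df["lft"].tolist() + df["rgt"].tolist())
    if values != list(range(1, 2 * n + 1)):
        raise ConsistencyError(
            "lft/rgt values are not a permutation of 1..2n"
        )
    nodes: list[TaxonNode] = []
    edges: list[tuple[str, str]] = []
    # stack of (node_id, rgt, depth) of currently open intervals
    stack: list[tuple[str, int, int]] = []
    for _, row in df.iterrows():
        nid, lft, rgt = str(row["node_id"]), int(row["lft"]), int(row["rgt"])
        if lft >= rgt:
            raise ConsistencyError(f"node {nid!r} has lft >= rgt")
        while stack and stack[-1][1] < lft:
            stack.pop()
        if stack:
            if rgt > stack[-1][1]:
                raise ConsistencyError(
                    f"interval of {nid!r} overlaps its enclosing interval"
                )
            edges.append((stack[-1][0], nid))
        depth = len(stack)
        if "depth" in df.columns and int(row["depth"]) != depth:
            raise ConsistencyError(
                f"stored depth of {nid!r} contradicts the lft/rgt nesting"
            )
        nodes.append(_node_from_row(row))
        stack.append((nid, rgt, depth))
    try:
        return build_taxonomy(nodes, edges)
    except StructureError as e:  # pragma: no cover - nesting implies a forest
        raise ConsistencyError(f"invalid nested-set table: {e}") from e


def _decode_closure(bundle: ModelTableBundle) -> Taxonomy | TaxonDag:
    nodes_df = bundle.table("nodes")
    hier = bundle.table("hierarchy")
    nodes = [_node_from_row(r) for _, r in nodes_df.iterrows()]
    node_ids = {n.id for n in nodes}

    if "relation_type" in hier.columns:
        rel = hier["relation_type"].fillna(PARENT_CHILD).astype(str)
    else:
        rel = pd.Series([PARENT_CHILD] * len(hier), index=hier.index)
    pc = hier[rel == PARENT_CHILD]
    typed_extra = [
        (str(r["ancestor_id"]), str(r["descendant_id"]), str(r["relation_type"]))
        for _, r in hier[rel != PARENT_CHILD].iterrows()
    ]

    given = {
        (str(r["ancestor_id"]), str(r["descendant_id"])): int(r["depth"])
        for _, r in pc.iterrows()
    }
    missing_self = sorted(n for n in node_ids if given.get((n, n)) != 0)
    if missing_self:
        raise ConsistencyError(
            f"closure table lacks depth-0 self rows for: {', '.join(missing_self)}"
        )
    edges = [(a, d) for (a, d), k in given.items() if k == 1]

    # recompute the closure from the direct edges and compare exactly
    report = validate_edges(edges, node_ids)
    if "CYCLE" in report.codes() or "DANGLING" in report.codes():
        raise ConsistencyError(f"closure depth-1 rows invalid: {report.violations}")
    dag = build_dag(nodes, edges)
    expected: dict[tuple[str, str], int] = {}
    for nid in dag.node_ids:
        for a, k in dag.ancestor_depths(nid).items():
            expected[(a, nid)] = k
    if given != expected:
        extra = sorted(set(given) - set(expected))
        absent = sorted(set(expected) - set(given))
        wrong = sorted(
            p for p in set(given) & set(expected) if given[p] != expected[p]
        )
        raise ConsistencyError(
            "closure table is not transitively consistent "
            f"(spurious={extra[:3]}, missing={absent[:3]}, bad depth={wrong[:3]})"
        )

    if typed_extra or not dag.is_uniparental():
        return build_dag(
            nodes, [(p, c, PARENT_CHILD) for p, c in edges] + typed_extra
        )
    # tree: restore sibling order from sort_key metadata via build_taxonomy
    return build_taxonomy(nodes, edges)
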