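"""Readers and writers for the tabular dialects of each hierarchy model.

Covers four families of interchange formats:

* the model tables themselves as CSV/TSV (one file per table; the closure
  model writes two — nodes and hierarchy);
* Darwin Core rows carrying ``higherClassification``: ancestor *names*
  joined highest→lowest by ``" | "`` (space, vertical bar, space), the
  convention real occurrence exports follow — a materialized path over
  names rather than ids;
* "biological" checklists with one column per rank (kingdom … species),
  the shape most databases actually distribute, and the recommended dual
  export that pairs such a checklist with a formalized closure table;
* Newick strings for interchange with phylogenetic tooling (topology and
  labels only, no branch lengths).

Model tables store opaque ids; rank columns and Darwin Core store names.
The dual export bridges the two by sharing one ``node_id`` set.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import pandas as pd

from .detect import DEFAULT_RANK_VOCAB  # noqa: F401  (re-exported convenience)
from .encodings import (
    ADJACENCY,
    CLOSURE,
    DEFAULT_DELIMITER,
    MATERIALIZED_PATH,
    MODELS,
    NESTED_SET,
    ModelTableBundle,
    encode_closure,
)
from .errors import (
    AmbiguousNameError,
    DuplicateRankOnPathError,
    HeaderError,
    MultirootError,
    OrphanPathError,
    ParseError,
)
from .model import TaxonNode, Taxonomy, build_taxonomy

DWC_DELIMITER = " | "

_REQUIRED_COLS = {
    ADJACENCY: {"nodes": ["node_id", "parent_id"]},
    MATERIALIZED_PATH: {"nodes": ["node_id", "path"]},
    NESTED_SET: {"nodes": ["node_id", "lft", "rgt", "depth"]},
    CLOSURE: {
        "nodes": ["node_id", "name", "rank"],
        "hierarchy": ["ancestor_id", "descendant_id", "depth"],
    },
}

_STR_COLS = (
    "node_id", "parent_id", "path", "name", "rank",
    "ancestor_id", "descendant_id", "relation_type",
)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={c: str for c in _STR_COLS})
    for c in df.columns:
        if c in _STR_COLS:
            df[c] = df[c].fillna("").replace("", pd.NA).astype(object)
    return df


def write_model_csv(bundle: ModelTableBundle, directory: str | Path) -> list[Path]:
    """Write each table of a bundle as ``<model>[_<table>].csv``.

    Single-table models produce one file named after the model; the
    closure model produces ``closure_table_nodes.csv`` and
    ``closure_table_hierarchy.csv``.  Column order is stable: the model's
    required columns first, metadata columns after.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for tname, df in bundle.tables.items():
        required = _REQUIRED_COLS[bundle.model][tname]
        cols = required + [c for c in df.columns if c not in required]
        fname = (
            f"{bundle.model}.csv"
            if bundle.table_count == 1
            else f"{bundle.model}_{tname}.csv"
        )
        out = directory / fname
        df[cols].to_csv(out, index=False)
        paths.append(out)
    return paths


def read_model_csv(
    files: str | Path | list[str | Path],
    model: str,
    delimiter: str = DEFAULT_DELIMITER,
) -> ModelTableBundle:
    """Read model table file(s) back into a validated bundle.

    The closure model expects two files (node table first, or any order —
    they are told apart by their headers) and accepts ``parent_id`` as an
    alias header for ``ancestor_id`` in the hierarchy table.  Missing
    required columns raise :class:`HeaderError`.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model: {model!r}")
    if isinstance(files, (str, Path)):
        files = [files]
    paths = [Path(f) for f in files]
    frames = [_read_table(p) for p in paths]

    if model == CLOSURE:
        if len(frames) != 2:
            raise HeaderError("closure_table needs exactly two files")
        tables: dict[str, pd.DataFrame] = {}
        for p, df in zip(paths, frames):
            if "descendant_id" in df.columns:
                if "ancestor_id" not in df.columns and "parent_id" in df.columns:
                    df = df.rename(columns={"parent_id": "ancestor_id"})
                _require(df, _REQUIRED_COLS[CLOSURE]["hierarchy"], p)
                tables["hierarchy"] = df
            else:
                _require(df, _REQUIRED_COLS[CLOSURE]["nodes"], p)
                tables["nodes"] = df
        if set(tables) != {"nodes", "hierarchy"}:
            raise HeaderError(
                "closure_table needs one node table and one hierarchy table"
            )
        return ModelTableBundle(CLOSURE, tables)

    if len(frames) != 1:
        raise HeaderError(f"{model} needs exactly one file")
    _require(frames[0], _REQUIRED_COLS[model]["nodes"], paths[0])
    return ModelTableBundle(model, {"nodes": frames[0]}, delimiter=delimiter)


def _require(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise HeaderError(f"{path.name}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Darwin Core


def write_dwc(tax: Taxonomy) -> pd.DataFrame:
    """Export as Darwin Core rows with ``higherClassification``.

    Each row joins the *names* of all ancestors (self excluded) with
    ``" | "``, highest rank first; roots carry an empty string.  Rows are
    emitted in hierarchical order.  Nodes without a name fall back to
    their id so the path stays resolvable.
    """

    def name_of(nid: str) -> str:
        return tax.node(nid).name or nid

    rows = [
        {
            "node_id": nid,
            "scientificName": name_of(nid),
            "higherClassification": DWC_DELIMITER.join(
                name_of(a) for a in tax.ancestors(nid)
            ),
        }
        for nid in tax.preorder()
    ]
    return pd.DataFrame(rows, columns=["node_id", "scientificName", "higherClassification"])


def read_dwc(rows: pd.DataFrame) -> Taxonomy:
    """Rebuild a taxonomy from Darwin Core rows by name-path closure.

    The reader is tolerant about delimiter spacing (``"|"`` with or
    without surrounding blanks).  Every parent prefix must itself occur as
    a row (:class:`OrphanPathError`); duplicate names within one sibling
    context are irresolvable (:class:`AmbiguousNameError`).  Node ids are
    taken from a ``node_id`` column when present, else derived from the
    name path.
    """
    name_col = _pick(rows, ("scientificName", "scientificname", "name"))
    path_col = _pick(rows, ("higherClassification", "higherclassification"))
    if name_col is None or path_col is None:
        raise HeaderError("Darwin Core input needs scientificName and higherClassification")
    has_ids = "node_id" in rows.columns

    by_path: dict[tuple[str, ...], str] = {}
    records: list[tuple[tuple[str, ...], str, str]] = []  # (full path, id, name)
    for i, row in rows.iterrows():
        name = str(row[name_col]).strip()
        raw = row[path_col]
        raw = "" if raw is None or pd.isna(raw) else str(raw)
        ancestors = tuple(t.strip() for t in raw.split("|") if t.strip())
        full = ancestors + (name,)
        if full in by_path:
            raise AmbiguousNameError(
                f"duplicate name path: {' | '.join(full)}"
            )
        nid = str(row["node_id"]) if has_ids else "/".join(full)
        by_path[full] = nid
        records.append((full, nid, name))

    nodes = [TaxonNode(nid, name=name) for _, nid, name in records]
    edges = []
    for full, nid, _ in records:
        if len(full) == 1:
            continue
        parent = by_path.get(full[:-1])
        if parent is None:
            raise OrphanPathError(
                f"no row for parent path: {' | '.join(full[:-1])}"
            )
        edges.append((parent, nid))
    return build_taxonomy(nodes, edges)


def _pick(df: pd.DataFrame, names) -> str | None:
    lower = {str(c).lower(): c for c in df.columns}
    for n in names:
        if n.lower() in lower:
            return lower[n.lower()]
    return None


# ---------------------------------------------------------------------------
# rank columns and the dual export


def write_rank_columns(
    tax: Taxonomy, ranks: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Flatten to a "biological" checklist with one column per rank.

    For each node and each configured rank, the cell holds the *name* of
    the unique ancestor-or-self carrying that rank (empty when no such
    ancestor exists).  Ancestors whose rank is unset or outside ``ranks``
    are skipped; their count is reported in ``df.attrs['unranked_skipped']``.
    Two ancestors sharing a rank on one path raise
    :class:`DuplicateRankOnPathError` — such a path is not representable
    in rank columns.
    """
    ranks = list(ranks)
    skipped = 0
    rows = []
    for nid in tax.preorder():
        chain = tax.ancestors(nid) + [nid]
        cells: dict[str, str] = {r: "" for r in ranks}
        for anc in chain:
            node = tax.node(anc)
            if node.rank is None or node.rank not in ranks:
                skipped += 1
                continue
            if cells[node.rank]:
                raise DuplicateRankOnPathError(
                    f"rank {node.rank!r} occurs twice on the path to {nid!r}"
                )
            cells[node.rank] = node.name or node.id
        rows.append(
            {"node_id": nid, "name": tax.node(nid).name or nid, **cells}
        )
    df = pd.DataFrame(rows, columns=["node_id", "name", *ranks])
    df.attrs["unranked_skipped"] = skipped
    return df


def write_dual_export(
    tax: Taxonomy, ranks: list[str] | tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, ModelTableBundle]:
    """The recommended two-part export: biologist-facing rank columns
    *plus* a formalized, analysis-ready closure table over one shared
    ``node_id`` set."""
    if ranks is None:
        present = [
            r for r in DEFAULT_RANK_VOCAB
            if any(n.rank == r for n in tax.nodes)
        ]
        ranks = present or list(DEFAULT_RANK_VOCAB[:7])
    checklist = write_rank_columns(tax, ranks)
    closure = encode_closure(tax)
    assert set(checklist["node_id"]) == set(closure.table("nodes")["node_id"])
    return checklist, closure


# ---------------------------------------------------------------------------
# Newick

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.\-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tax: Taxonomy) -> str:
    """Serialize a single-rooted taxonomy as a Newick string.

    Labels are node ids (quoted when needed); sibling order is preserved;
    no branch lengths are emitted.  Forests raise :class:`MultirootError`.
    """
    roots = tax.roots
    if len(roots) != 1:
        raise MultirootError(
            f"Newick needs a single root; taxonomy has {len(roots)}"
        )

    def serialize(nid: str) -> str:
        children = tax.children_of(nid)
        label = _quote(nid)
        if not children:
            return label
        return "(" + ",".join(serialize(c) for c in children) + ")" + label

    return serialize(roots[0]) + ";"


def read_newick(text: str) -> Taxonomy:
    """Parse a Newick string into a taxonomy (ids = labels, order kept).

    Branch lengths, if present, are discarded; unlabeled internal nodes
    get synthetic ids.  Malformed input raises :class:`ParseError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:
        raise ParseError(f"invalid Newick: {e}") from e

    nodes: list[TaxonNode] = []
    edges: list[tuple[str, str]] = []
    counter = 0
    ids: dict[int, str] = {}

    def label_of(nd) -> str | None:
        if nd.taxon is not None and nd.taxon.label is not None:
            return nd.taxon.label
        return nd.label

    for nd in tree.preorder_node_iter():
        nonlocal_label = label_of(nd)
        if nonlocal_label is None:
            counter += 1
            nonlocal_label = f"_node{counter}"
        ids[id(nd)] = nonlocal_label
        nodes.append(TaxonNode(nonlocal_label, name=nonlocal_label))
        if nd.parent_node is not None:
            edges.append((ids[id(nd.parent_node)], nonlocal_label))
    if not nodes:
        raise ParseError("empty Newick string")
    return build_taxonomy(nodes, edges)
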