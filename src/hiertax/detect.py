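"""Classify a tabular taxon export by the hierarchy model it carries.

Biodiversity databases publish taxon lists in wildly different shapes:
some carry a formalized hierarchy (adjacency list, materialized path,
nested set, closure table), some only a "biological" hierarchy of rank
columns (kingdom, family, genus, …), and some none at all.  Given one or
two tables with headers, :func:`detect_model` runs a fixed cascade of
structural tests — most specific first, so a closure table is never
mistaken for the adjacency list its depth-1 rows resemble — and returns
the verdict together with the full evidence trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd

from .errors import EmptyInputError
from .model import validate_edges

ADJACENCY = "adjacency_list"
MATERIALIZED_PATH = "materialized_path"
NESTED_SET = "nested_set"
CLOSURE = "closure_table"
RANK_BIOLOGICAL = "rank_biological"
NONE = "none"

#: Default controlled vocabulary of rank column names (Linnaean ranks and
#: common refinements); matching is case-insensitive.  Configurable because
#: nomenclatural traditions differ between organism groups.
DEFAULT_RANK_VOCAB = (
    "domain", "superkingdom", "kingdom", "subkingdom",
    "superphylum", "phylum", "subphylum", "division", "subdivision",
    "superclass", "class", "subclass", "infraclass",
    "superorder", "order", "suborder", "infraorder",
    "superfamily", "family", "subfamily", "tribe", "subtribe",
    "genus", "subgenus", "section", "series",
    "species", "subspecies", "variety", "subvariety", "form",
)

_ID_COL_NAMES = ("node_id", "taxon_id", "taxonid", "id", "key", "taxonkey")
_NAME_COL_NAMES = ("scientificname", "name", "taxon_name", "taxon", "label")
_PATH_DELIMITERS = (" | ", "|", "/", ";", ".")


@dataclass(frozen=True)
class EvidenceItem:
    test: str
    passed: bool
    detail: str


@dataclass
class ModelClassification:
    """Detector verdict plus its evidence trail.

    ``confidence`` is the fraction of structural checks run for the winning
    verdict that passed (0.0 for ``none``); ``evidence`` records every test
    performed, in order.
    """

    verdict: str
    confidence: float
    evidence: list[EvidenceItem] = field(default_factory=list)


def _find_col(df: pd.DataFrame, names: Sequence[str]) -> str | None:
    lower = {str(c).strip().lower(): c for c in df.columns}
    for n in names:
        if n in lower:
            return lower[n]
    return None


def _id_column(df: pd.DataFrame, id_col: str | None) -> str | None:
    if id_col is not None and id_col in df.columns:
        return id_col
    col = _find_col(df, _ID_COL_NAMES)
    if col is not None:
        return col
    # fall back: first column whose values are unique
    for c in df.columns:
        vals = df[c].dropna().astype(str)
        if len(vals) == len(df) and vals.is_unique:
            return c
    return None


def _closure_check(df: pd.DataFrame, evidence: list[EvidenceItem]) -> bool:
    anc = _find_col(df, ("ancestor_id", "ancestor", "parent_id", "parentid"))
    dec = _find_col(df, ("descendant_id", "descendant", "child_id", "node_id"))
    if anc is None or dec is None or anc == dec:
        evidence.append(
            EvidenceItem(
                "closure:columns", False, "no ancestor/descendant column pair"
            )
        )
        return False
    dep = _find_col(df, ("depth", "distance", "path_length", "generations"))
    pairs = list(
        zip(df[anc].astype(str), df[dec].astype(str), strict=True)
    )
    nodes = {d for _, d in pairs} | {a for a, _ in pairs}
    has_self = all((n, n) in set(pairs) for n in nodes)
    evidence.append(
        EvidenceItem(
            "closure:self_rows", has_self, "every node has an (x, x) self row"
            if has_self else "self rows missing for some nodes",
        )
    )
    if not has_self:
        return False
    if dep is not None:
        try:
            depth = {
                (a, d): int(k)
                for (a, d), k in zip(
                    pairs, pd.to_numeric(df[dep], errors="raise"), strict=True
                )
            }
        except (ValueError, TypeError):
            evidence.append(
                EvidenceItem("closure:depth", False, "depth column not numeric")
            )
            return False
        if any(depth.get((n, n)) != 0 for n in nodes):
            evidence.append(
                EvidenceItem("closure:depth", False, "self rows not at depth 0")
            )
            return False
        edges = [(a, d) for (a, d), k in depth.items() if k == 1]
    else:
        edges = None
    # transitivity over the strict pair set
    strict = {(a, d) for a, d in pairs if a != d}
    anc_of: dict[str, set[str]] = {}
    for a, d in strict:
        anc_of.setdefault(d, set()).add(a)
    transitive = all(
        anc_of.get(a, set()) <= anc_of.get(d, set())
        for a, d in strict
    )
    evidence.append(
        EvidenceItem(
            "closure:transitivity",
            transitive,
            "ancestor sets are transitively closed"
            if transitive
            else "pairs implied by transitivity are missing",
        )
    )
    if not transitive:
        return False
    if edges is not None:
        ok = validate_edges(edges).ok
        evidence.append(
            EvidenceItem(
                "closure:depth1_acyclic", ok,
                "depth-1 rows form an acyclic graph" if ok else "depth-1 rows cyclic",
            )
        )
        if not ok:
            return False
    return True


def _nested_check(
    df: pd.DataFrame, id_col: str | None, evidence: list[EvidenceItem]
) -> bool:
    int_cols = [
        c
        for c in df.columns
        if c != id_col
        and pd.api.types.is_numeric_dtype(df[c])
        and df[c].notna().all()
        and (pd.to_numeric(df[c]) % 1 == 0).all()
    ]
    named = (
        _find_col(df, ("lft", "left", "lhs")),
        _find_col(df, ("rgt", "right", "rhs")),
    )
    candidates: list[tuple[str, str]] = []
    if named[0] in int_cols and named[1] in int_cols:
        candidates.append(named)  # type: ignore[arg-type]
    candidates.extend(
        (a, b) for a, b in combinations(int_cols, 2) if (a, b) != named
    )
    n = len(df)
    for a, b in candidates:
        lo = pd.to_numeric(df[a]).astype(int)
        hi = pd.to_numeric(df[b]).astype(int)
        if (lo > hi).all():
            lo, hi = hi, lo
        if not (lo < hi).all():
            continue
        if sorted(lo.tolist() + hi.tolist()) != list(range(1, 2 * n + 1)):
            continue
        if _properly_nested(lo.tolist(), hi.tolist()):
            evidence.append(
                EvidenceItem(
                    "nested_set:intervals",
                    True,
                    f"columns ({a}, {b}) form a properly nested 1..2n permutation",
                )
            )
            return True
    evidence.append(
        EvidenceItem(
            "nested_set:intervals",
            False,
            "no integer column pair forms nested 1..2n intervals",
        )
    )
    return False


def _properly_nested(lft: list[int], rgt: list[int]) -> bool:
    stack: list[int] = []
    for lo, hi in sorted(zip(lft, rgt)):
        while stack and stack[-1] < lo:
            stack.pop()
        if stack and hi > stack[-1]:
            return False
        stack.append(hi)
    return True


def _path_check(
    df: pd.DataFrame, id_col: str | None, evidence: list[EvidenceItem]
) -> bool:
    path_col = _find_col(
        df, ("higherclassification", "path", "ancestor_path", "hierarchy")
    )
    str_cols = [
        c
        for c in df.columns
        if df[c].dtype == object and c != id_col
    ]
    candidates = ([path_col] if path_col is not None else []) + [
        c for c in str_cols if c != path_col
    ]
    label_cols = [c for c in ([id_col] if id_col else []) + str_cols]
    for col in candidates:
        paths = df[col].fillna("").astype(str)
        nonempty = paths[paths != ""].tolist()
        if not nonempty:
            continue
        for delim in _PATH_DELIMITERS:
            # a path column must actually join something: require >= 1
            # multi-token value, else it is indistinguishable from a
            # plain parent pointer
            if not any(delim in p for p in nonempty):
                continue

            def tokens(p: str) -> tuple[str, ...]:
                return tuple(t.strip() for t in p.split(delim)) if p else ()

            for label_col in label_cols:
                if label_col == col:
                    continue
                labels = df[label_col].fillna("").astype(str)
                rows = {
                    (tokens(p), l.strip()) for p, l in zip(paths, labels)
                }
                ok = all(
                    (tokens(p)[:-1], tokens(p)[-1]) in rows for p in nonempty
                )
                if ok:
                    evidence.append(
                        EvidenceItem(
                            "materialized_path:prefix_closure",
                            True,
                            f"column {col!r} is prefix-closed over "
                            f"labels {label_col!r} (delimiter {delim!r})",
                        )
                    )
                    return True
    evidence.append(
        EvidenceItem(
            "materialized_path:prefix_closure",
            False,
            "no column is a delimiter-joined, prefix-closed path",
        )
    )
    return False


def _adjacency_check(
    df: pd.DataFrame, id_col: str | None, evidence: list[EvidenceItem]
) -> bool:
    if id_col is None:
        evidence.append(
            EvidenceItem("adjacency:id_column", False, "no id column identified")
        )
        return False
    ids = set(df[id_col].dropna().astype(str))
    parent_named = _find_col(
        df, ("parent_id", "parentid", "parent", "parentnameusageid")
    )
    candidates = ([parent_named] if parent_named else []) + [
        c for c in df.columns if c not in (id_col, parent_named)
    ]
    for col in candidates:
        vals = df[col].fillna("").astype(str)
        filled = vals[vals != ""]
        if filled.empty or not set(filled) <= ids:
            continue
        if (vals.values == df[id_col].astype(str).values).any():
            continue  # self-loop: not a parent pointer
        edges = [
            (str(p), str(n))
            for p, n in zip(vals, df[id_col].astype(str))
            if p != ""
        ]
        if validate_edges(edges).ok:
            evidence.append(
                EvidenceItem(
                    "adjacency:parent_reference",
                    True,
                    f"column {col!r} references {id_col!r} acyclically",
                )
            )
            return True
    evidence.append(
        EvidenceItem(
            "adjacency:parent_reference",
            False,
            "no column acyclically references the id column",
        )
    )
    return False


def _rank_check(
    df: pd.DataFrame,
    id_col: str | None,
    rank_vocab: Sequence[str],
    evidence: list[EvidenceItem],
) -> bool:
    vocab = {r.lower() for r in rank_vocab}
    rank_cols = [c for c in df.columns if str(c).strip().lower() in vocab]
    passed = bool(rank_cols)
    evidence.append(
        EvidenceItem(
            "rank_biological:rank_columns",
            passed,
            f"rank-named columns: {', '.join(map(str, rank_cols))}"
            if passed
            else "no rank-named columns",
        )
    )
    return passed


def detect_model(
    tables: Sequence[pd.DataFrame] | pd.DataFrame,
    *,
    id_col: str | None = None,
    rank_vocab: Sequence[str] = DEFAULT_RANK_VOCAB,
) -> ModelClassification:
    """Classify one or two taxon tables by hierarchy encoding.

    The cascade, most specific first:

    1. a table with ancestor/descendant(+depth) columns whose rows contain
       every self pair and are transitively closed → ``closure_table``;
    2. an integer column pair forming a properly nested permutation of
       1..2n → ``nested_set``;
    3. a string column of delimiter-joined paths closed under the
       parent-prefix relation (incl. Darwin Core ``higherClassification``
       with its " | " delimiter) → ``materialized_path``;
    4. a column acyclically referencing the table's own id column →
       ``adjacency_list``;
    5. rank-named columns only (kingdom … species) → ``rank_biological``
       (a "biological", relationally informal hierarchy);
    6. otherwise → ``none``.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    tables = list(tables)
    if not tables or all(t.empty for t in tables):
        raise EmptyInputError("detector needs at least one non-empty table")
    if not 1 <= len(tables) <= 2:
        raise ValueError("detect_model accepts one or two tables")

    evidence: list[EvidenceItem] = []

    def verdict_for(name: str, test: str) -> ModelClassification:
        relevant = [e for e in evidence if e.test.startswith(test)]
        conf = (
            sum(e.passed for e in relevant) / len(relevant) if relevant else 1.0
        )
        return ModelClassification(name, conf, evidence)

    for df in tables:
        if not df.empty and _closure_check(df, evidence):
            return verdict_for(CLOSURE, "closure:")
    for df in tables:
        if not df.empty and _nested_check(df, _id_column(df, id_col), evidence):
            return verdict_for(NESTED_SET, "nested_set:")
    for df in tables:
        if not df.empty and _path_check(df, _id_column(df, id_col), evidence):
            return verdict_for(MATERIALIZED_PATH, "materialized_path:")
    for df in tables:
        if not df.empty and _adjacency_check(df, _id_column(df, id_col), evidence):
            return verdict_for(ADJACENCY, "adjacency:")
    for df in tables:
        if not df.empty and _rank_check(df, _id_column(df, id_col), rank_vocab, evidence):
            return verdict_for(RANK_BIOLOGICAL, "rank_biological:")
    return ModelClassification(NONE, 0.0, evidence)
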