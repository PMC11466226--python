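# Methods

## Scope and the canonical form

`hiertax` treats a taxonomy as a **rooted forest with ordered
siblings**: every node has at most one parent, the parent relation is
acyclic, and each sibling set carries a total order.  Multiple roots are
allowed because real exports routinely contain several kingdoms.
Biological information — scientific name, rank — is node *metadata*;
identity lives in an opaque string id, so renaming or re-ranking a taxon
never changes the structure.  Hybrid taxa break the single-parent rule,
so a second structure, `TaxonDag`, permits multiple parents and typed
edges.  The relation-type vocabulary is an open string set with four
reserved values (`parent_child`, `part_of`, `congruent`, `overlap`);
only `parent_child` edges participate in ancestry, and acyclicity is
enforced over those edges alone.  Whether non-hierarchical relation
types may form cycles among themselves is deliberately left
unconstrained — nothing in their semantics requires a partial order.

Sibling order is resolved as: explicit `sort_key` first, then input
(edge/row) order, then lexicographic id.  Duplicate sort keys among
siblings are tolerated and broken by the later keys rather than
rejected: edits such as reparenting can legitimately bring two siblings
with equal keys together, and failing there would make history replay
brittle.

## The four encodings

* **Adjacency list** — one row per node with `parent_id` (empty for
  roots).  Rows are written in pre-order so that row order alone
  reproduces sibling order even without sort keys.
* **Materialized path** — per node, the ids of its ancestors
  highest→lowest joined by a delimiter (default `"|"`), self excluded,
  roots empty.  Ids rather than names: names drift, ids are stable
  (name-based paths exist separately in the Darwin Core writer).  An id
  containing the delimiter is an error, not an escape sequence.
* **Nested set** — a double-visit depth-first traversal assigns `lft`
  on entry and `rgt` on exit, starting at 1 and numbering a forest's
  components consecutively in root order, so over n nodes the values
  are a permutation of 1..2n and every invariant can be checked
  globally.  The redundant `depth` column (root = 0) is stored because
  it turns direct-parent and direct-child lookups into single
  predicates.
* **Closure table** — two tables, nodes and hierarchy, the hierarchy
  holding one `(ancestor_id, descendant_id, depth)` row per reachable
  pair including depth-0 self rows.  Self rows are required: they make
  "subtree including its root" a single equality filter.  On
  multiparental DAGs the table stays a *set* by storing the minimum
  path length per pair rather than one row per path.  Non-hierarchical
  typed edges are carried as extra rows tagged with their
  `relation_type` at depth 1.

Encoders attach `name`, `rank` and `sort_key` as trailing metadata
columns by default, which is what makes `decode(encode(t)) == t` exact
— including sibling order — for every model.  Decoders validate before
building: nested-set tables must be a 1..2n permutation with properly
nested intervals and consistent depths; closure tables must contain all
self rows and exactly the transitive closure of their depth-1 rows
(checked by recomputing the closure and comparing as sets); path tables
must contain a consistent parent row for every non-empty path;
adjacency tables must be acyclic.  A closure bundle whose depth-1 rows
give some node two parents decodes to a `TaxonDag` instead of a
`Taxonomy`.

## Query semantics

Eight tasks (all parents, direct parent, subtree exclusive/inclusive,
direct children, is-leaf, is-root, hierarchical sort, branch
aggregation) run on five backends: the canonical form and the four
encodings.  Each backend uses its model's native access path — the
nested-set backend evaluates the literal interval predicates
(`lft < node.lft && rgt > node.rgt`, leaf ⇔ `lft == rgt − 1`, …), the
closure backend filters rows, the adjacency backend iterates parent
pointers, the path backend does string prefix matching.  No backend is
allowed to convert to another model internally; the equivalence of all
five on random trees is itself one of the package's guarantees.

On multiparental backends `direct_parent` raises rather than silently
picking one parent (`all_direct_parents` exists for that case), and
`all_parents` returns the union of ancestors.  Because no root→node
chain exists on a DAG, ancestors are ordered by decreasing minimum
distance to the node with id tie-breaks — a deterministic topological
order that coincides with the root-first chain on trees.

Branch aggregation folds user-supplied per-node values over the
subtree *including* its root (the typical "occurrences of the species
including its subspecies" request) and reports every uncovered member
rather than guessing zeros.

## The detector

`detect_model` classifies one or two header-bearing tables by a fixed
most-specific-first cascade: closure (ancestor/descendant columns, all
self rows present, pair set transitively closed, depth-1 rows acyclic)
→ nested set (some integer column pair forms a properly nested 1..2n
permutation) → materialized path (a string column of delimiter-joined
paths closed under the parent-prefix relation, with the path's last
token matching another row's label; delimiters tried include the Darwin
Core `" | "`) → adjacency (a column acyclically referencing the table's
own id column) → rank columns (column names drawn from a configurable
rank vocabulary; the default covers Linnaean principal ranks plus
common refinements) → none.  The order matters: a closure hierarchy
also contains an id-referencing column and would otherwise read as an
adjacency list.  The verdict carries the full evidence trail and a
confidence equal to the fraction of the winning test's sub-checks that
passed.

Two structural limits follow from the definitions, not the
implementation: a materialized-path table whose deepest path has a
single token is indistinguishable from an adjacency list, and the
detector requires at least one multi-token path; headerless edge
matrices (as produced by some phylogenetic packages) are not accepted.

## Versioned closure tables

`init_versioned` stamps the closure of a taxonomy as version 1.  Edits
(`add_node`, `move_node`, `delete_node`) never rewrite rows: superseded
rows get an `invalidated_version`, new rows a `created_version`, and
the whole-tree version increases by one per edit.  A move invalidates
every pairing of the moved branch with its former strict ancestors and
creates the pairings with the new ones; within-branch rows and self
rows are untouched (self rows are immortal except under deletion).
Deletion is leaf-only unless `cascade` is passed — a safety default.
`snapshot(v)` rebuilds the tree from the rows valid at `v`;
`diff(v1, v2)` reports nodes and direct edges added/removed *plus*
every affected transitive ancestor pairing, because moving a taxon also
changes the composition of every group above its old and new positions.
Version numbers are monotone integers over the entire tree; wall-clock
timestamps or editor identities can be attached externally keyed by
version.

## Interchange formats

* **Model CSVs** — stable column orders (`node_id,parent_id`;
  `node_id,path`; `node_id,lft,rgt,depth`; closure
  `node_id,name,rank` + `ancestor_id,descendant_id,depth[,relation_type]`),
  UTF-8, mandatory header, TSV by file extension.  The closure reader
  accepts `parent_id` as an alias header for `ancestor_id`, a common
  naming in published schemas.
* **Darwin Core** — `higherClassification` joins ancestor *names*
  highest→lowest with exactly `" | "`; the reader tolerates missing
  spaces around the bar.  All ancestors are included, ranked or not.
  Reading rebuilds the tree by prefix closure over name paths and
  refuses duplicate sibling names (ambiguous) or paths whose parent
  prefix has no row (orphans).
* **Rank columns** — one column per configured rank holding the name of
  the unique ancestor-or-self at that rank; unranked ancestors are
  skipped and counted in `df.attrs["unranked_skipped"]`; two ancestors
  sharing a rank on one path are an error because the flat form cannot
  represent them.  The dual export pairs this biologist-facing
  checklist with a closure table over the same `node_id` set.
* **Newick** — topology and labels only, sibling order preserved,
  single root required; labels outside `[A-Za-z0-9_.-]` are quoted.
  Parsing goes through dendropy (underscores preserved); serialization
  is a direct pre-order walk.

## Synthetic data

The generator attaches each new node to a uniformly chosen existing
node that still has spare capacity, bounded by `max_children` (default
6) and `max_depth` (default 7) — defaults wide enough to produce both
bushy and chain-like shapes at the test sizes (tens to two hundred
nodes).  Ranks follow the Linnaean ladder by depth; names differ from
ids; sort keys record attachment order.  DAG mode first grows a tree,
then gives an expected `hybrid_fraction` of non-root nodes a second
parent drawn from outside the set of nodes already reachable from them
(over all edges added so far), which preserves acyclicity by
construction.  Each call owns a private `random.Random(seed)` stream,
so corpora are exactly reproducible and independent of global state.

What the generator does *not* emulate: realistic taxon-size
distributions, synonymy, name misspellings, or partially filled rank
ladders.  Passing tests therefore demonstrate structural correctness of
the encodings, queries, detector and history on well-formed input — not
robustness to the name-level noise of real aggregated checklists.

## Problem sizes and numerical choices

The automated checks use 200 random taxonomies (≤ 200 nodes) for the
conversion matrix, 50 trees (≤ 100 nodes) for cross-backend query
equivalence, 100 seeds for nested-set invariants, 50 for closure
invariants, 100 taxonomies for detector self-consistency, 20 random
10-edit histories for versioning, and 10 DAGs (80 nodes,
hybrid fraction 0.15) for the multiparental gate — sizes chosen to
exercise every code path many times over while keeping the whole suite
comfortably interactive.  All comparisons are exact (set and sequence
equality); there are no floating-point tolerances anywhere in the
package.

## Known limitations

* Queries run in memory over pandas tables; nothing is pushed to a SQL
  engine, and the relative *performance* folklore of the four models is
  neither measured nor asserted.
* Alternative concurrent classifications are out of scope: one
  `VersionedClosure` tracks one linear edit history; divergent
  histories cannot be merged.
* The Darwin Core reader requires names to be unique within their
  sibling context; real exports with homonyms need ids.
* Detector verdicts are structural: a table that happens to satisfy a
  model's invariants is reported as that model even if its producer
  intended otherwise.
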