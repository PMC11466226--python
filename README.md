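# hiertax

**Relational encodings of taxon hierarchies, with lossless conversion,
a uniform query suite, an encoding detector, and versioned change
tracking.**

Every biodiversity database has to store a taxon hierarchy, and the
exports that reach researchers encode it in one of a handful of
relational shapes — when they encode it at all.  `hiertax` implements
the four standard relational models of a tree side by side, so that a
checklist can be converted between them, queried identically in each,
and an arbitrary tabular taxon export can be classified by the model it
carries:

| Model | Mechanism | Tables |
|---|---|---|
| **Adjacency List** | each node stores its parent's id | 1 |
| **Materialized Path** | each node stores the delimiter-joined ids of all its ancestors | 1 |
| **Nested Set** | a double-visit depth-first traversal assigns each node an interval (*lft*, *rgt*); descendants nest strictly inside ancestors | 1 |
| **Closure Table** | one row per (ancestor, descendant, depth) pair, self rows at depth 0, kept separate from the node table | 2 |

Over *n* nodes the nested-set values form a permutation of 1..2*n*, a
node is a leaf exactly when *lft* = *rgt* − 1, and the closure table of
a tree has Σᵢ(depthᵢ + 1) rows.  Only the closure table can hold
multiparental structures (hybrid taxa with two parents) and typed
relationships beyond parent–child (`part_of`, `congruent`, `overlap`);
the other three encoders refuse such input.  Names and ranks are node
*metadata* — hierarchy structure never depends on them.

The package is aimed at biodiversity informaticians who build or
consume checklist exports: it also reads and writes Darwin Core
`higherClassification` (a materialized path over names, joined by
`" | "`), flattens a tree to "biological" rank columns
(kingdom … species), produces the recommended dual export (rank
checklist + formalized closure table), and exchanges Newick strings
with phylogenetic tooling.

## Worked example

```python
import hiertax as hx

tax = hx.fixture_fig1()           # A → {B, C}, C → D; B before C

print(hx.encode_nested_set(tax).table("nodes")[["node_id", "lft", "rgt", "depth"]])
#   node_id  lft  rgt  depth
# 0       A    1    8      0
# 1       B    2    3      1
# 2       C    4    7      1
# 3       D    5    6      2

hier = hx.encode_closure(tax).table("hierarchy")
print(len(hier))                  # 8  (4 self rows + A→B, A→C, C→D, A→D)

print(hx.all_parents(hx.encode_nested_set(tax), "D"))   # ['A', 'C']
print(hx.subtree(tax, "C", include_root=True))          # {'C', 'D'}
print(hx.write_newick(tax))                             # (B,(D)C)A;
```

The nested-set row `A(1, 8)` says the root's interval spans the whole
tree; `D(5, 6)` nests inside `C(4, 7)` inside `A`, and `lft == rgt - 1`
marks `B` and `D` as leaves.  The closure table's 8 rows are the four
depth-0 self links plus every ancestor pair, so "all parents of D" is a
single filter (`descendant_id == "D" & depth > 0`) — no recursion.

Detecting what an export contains:

```python
bundle = hx.encode_closure(tax)
hx.detect_model(list(bundle.tables.values())).verdict   # 'closure_table'
hx.detect_model(hx.write_dwc(tax)).verdict              # 'materialized_path'
```

Tracking changes with a versioned closure table:

```python
from hiertax.versioning import ChangeOp, init_versioned, diff

vc = init_versioned(tax)
vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
vc.snapshot(1).parent_of("D")     # 'C'  — history preserved
vc.snapshot(2).parent_of("D")     # 'A'
diff(vc, 1, 2).pairs_removed      # [('A', 'D', 2), ('C', 'D', 1)]
```

A command-line interface (`hiertax generate | convert | detect | query |
snapshot | diff`) wraps the same functions; see `hiertax --help`.

## Documentation

`docs/methods.md` describes the encodings, the query semantics on each
model, the detector's test cascade, the versioning model and the
synthetic generator, including the numerical and design choices.
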