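"""Versioned closure tables: append-only history, snapshots and diffs."""

import random

import pytest

import hiertax as hx
from hiertax.versioning import ChangeOp, ChangeSet, diff, init_versioned, snapshot
from conftest import brute_force_closure


def closure_set(tax):
    return brute_force_closure(tax)


class TestInit:
    def test_fig1_eight_rows_at_version_one(self, fig1):
        vc = init_versioned(fig1)
        assert vc.current_version == 1
        assert len(vc.rows) == 8
        assert all(r.created_version == 1 and r.invalidated_version is None for r in vc.rows)

    def test_singleton_single_self_row(self):
        t = hx.build_taxonomy(["X"], [])
        vc = init_versioned(t)
        assert [(r.ancestor_id, r.descendant_id, r.depth) for r in vc.rows] == [("X", "X", 0)]

    def test_snapshot_at_creation_is_identity(self, fig1):
        assert snapshot(init_versioned(fig1), 1) == fig1


class TestApplyChange:
    def test_move_invalidates_old_pairings(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
        assert vc.current_version == 2
        stamped = {
            (r.ancestor_id, r.descendant_id, r.depth): r.invalidated_version
            for r in vc.rows
            if r.invalidated_version is not None
        }
        assert stamped == {("C", "D", 1): 2, ("A", "D", 2): 2}
        created = [
            (r.ancestor_id, r.descendant_id, r.depth)
            for r in vc.rows
            if r.created_version == 2
        ]
        assert created == [("A", "D", 1)]

    def test_move_into_own_branch_rejected(self, fig1):
        vc = init_versioned(fig1)
        with pytest.raises(hx.InvalidMoveError):
            vc.apply_change(ChangeOp("move_node", node_id="C", parent_id="D"))

    def test_add_node_creates_ancestor_walk_rows(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(
            ChangeOp("add_node", node=hx.TaxonNode("E", name="E"), parent_id="B")
        )
        created = sorted(
            (r.ancestor_id, r.descendant_id, r.depth)
            for r in vc.rows
            if r.created_version == 2
        )
        assert created == [("A", "E", 2), ("B", "E", 1), ("E", "E", 0)]

    def test_delete_requires_leaf_unless_cascade(self, fig1):
        vc = init_versioned(fig1)
        with pytest.raises(ValueError):
            vc.apply_change(ChangeOp("delete_node", node_id="C"))
        vc.apply_change(ChangeOp("delete_node", node_id="C", cascade=True))
        assert set(snapshot(vc, 2).node_ids) == {"A", "B"}
        assert set(snapshot(vc, 1).node_ids) == {"A", "B", "C", "D"}

    def test_unknown_node_rejected(self, fig1):
        vc = init_versioned(fig1)
        with pytest.raises(hx.UnknownNodeError):
            vc.apply_change(ChangeOp("move_node", node_id="Z", parent_id="A"))


class TestSnapshot:
    def test_historical_states_preserved(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
        assert snapshot(vc, 1) == fig1
        s2 = snapshot(vc, 2)
        assert s2.parent_of("D") == "A"
        assert set(s2.node_ids) == set(fig1.node_ids)

    @pytest.mark.parametrize("bad", [0, 5])
    def test_out_of_range_version(self, fig1, bad):
        with pytest.raises(hx.UnknownVersionError):
            snapshot(init_versioned(fig1), bad)


class TestDiff:
    def test_move_diff_lists_all_affected_pairings(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
        cs = diff(vc, 1, 2)
        assert cs.edges_removed == [("C", "D")]
        assert cs.edges_added == [("A", "D")]
        assert set(cs.pairs_removed) == {("C", "D", 1), ("A", "D", 2)}
        assert set(cs.pairs_added) == {("A", "D", 1)}

    def test_identity_diff_empty(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
        assert diff(vc, 1, 1).empty
        assert diff(vc, 2, 2).empty

    def test_diff_inverts(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
        fwd, back = diff(vc, 1, 2), diff(vc, 2, 1)
        assert fwd.edges_added == back.edges_removed
        assert fwd.edges_removed == back.edges_added
        assert fwd.pairs_added == back.pairs_removed

    def test_apply_composes_snapshots(self, fig1):
        vc = init_versioned(fig1)
        vc.apply_change(ChangeOp("move_node", node_id="D", parent_id="A"))
        vc.apply_change(ChangeOp("add_node", node=hx.TaxonNode("E"), parent_id="D"))
        for v1 in (1, 2, 3):
            for v2 in (1, 2, 3):
                got = diff(vc, v1, v2).apply_to(snapshot(vc, v1))
                assert got.topology_equal(snapshot(vc, v2))


def random_ops(rng, vc, n_ops):
    """Draw valid random edits against the current state."""
    ops = []
    counter = [0]
    for _ in range(n_ops):
        tax = snapshot(vc, vc.current_version)
        kind = rng.choice(["add_node", "move_node", "move_node", "delete_node"])
        if kind == "add_node" or len(tax) < 3:
            counter[0] += 1
            op = ChangeOp(
                "add_node",
                node=hx.TaxonNode(f"new{counter[0]}", name=f"new{counter[0]}"),
                parent_id=rng.choice(tax.node_ids),
            )
        elif kind == "move_node":
            nid = rng.choice(tax.node_ids)
            candidates = [
                x for x in tax.node_ids
                if x != nid and x not in tax.descendants(nid)
            ]
            if not candidates:
                continue
            op = ChangeOp("move_node", node_id=nid, parent_id=rng.choice(candidates))
        else:
            leaves = tax.leaves
            if len(leaves) <= 1:
                continue
            op = ChangeOp("delete_node", node_id=rng.choice(leaves))
        vc.apply_change(op)
        ops.append(op)
    return ops


def ref_apply(parents: dict, op: ChangeOp) -> None:
    """Independent replay: plain parent-pointer edits, no closure logic."""
    if op.kind == "add_node":
        parents[op.node.id] = op.parent_id
    elif op.kind == "move_node":
        parents[op.node_id] = op.parent_id
    elif op.kind == "delete_node":
        del parents[op.node_id]


def ref_closure(parents: dict) -> set[tuple[str, str, int]]:
    out = set()
    for n in parents:
        d, cur = 0, n
        while cur is not None:
            out.add((cur, n, d))
            cur = parents.get(cur)
            d += 1
    return out


class TestAppendOnlyHistory:
    @pytest.mark.parametrize("seed", range(5))
    def test_history_replays_independently_recomputed_closures(
        self, random_taxonomy, seed
    ):
        """After any edit sequence, rows valid at each past version must
        reproduce the closure recomputed from scratch on a replayed tree."""
        rng = random.Random(seed)
        t = random_taxonomy(seed, n_nodes=15)
        vc = init_versioned(t)
        parents = {n: t.parent_of(n) for n in t.node_ids}
        expected = [ref_closure(parents)]
        for op in random_ops(rng, vc, 10):
            ref_apply(parents, op)
            expected.append(ref_closure(parents))
        assert vc.current_version == len(expected)
        for v in range(1, vc.current_version + 1):
            valid = {
                (r.ancestor_id, r.descendant_id, r.depth)
                for r in vc.rows_at(v)
            }
            assert valid == expected[v - 1]
            # the snapshot rebuilt from depth-0/1 rows implies the same closure
            assert closure_set(snapshot(vc, v)) == expected[v - 1]

    @pytest.mark.parametrize("seed", range(3))
    def test_diff_compose_over_random_histories(self, random_taxonomy, seed):
        rng = random.Random(100 + seed)
        vc = init_versioned(random_taxonomy(seed + 3, n_nodes=12))
        random_ops(rng, vc, 8)
        top = vc.current_version
        for v1 in (1, top // 2 or 1, top):
            for v2 in (1, top):
                got = diff(vc, v1, v2).apply_to(snapshot(vc, v1))
                assert got.topology_equal(snapshot(vc, v2))
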