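import pytest

import hiertax as hx


@pytest.fixture
def fig1() -> hx.Taxonomy:
    """Four-node example: A → {B, C} (B first), C → D."""
    return hx.fixture_fig1()


@pytest.fixture
def random_taxonomy():
    """Factory for seeded random taxonomies of a given size."""

    def make(seed: int, n_nodes: int = 40, **kwargs) -> hx.Taxonomy:
        return hx.generate_taxonomy(
            hx.GenParams(n_nodes=n_nodes, seed=seed, **kwargs)
        )

    return make


def parent_map(tax: hx.Taxonomy) -> dict[str, str]:
    """Oracle helper: parent pointers straight from the edge list."""
    return {c: p for p, c in tax.edges()}


def walk_ancestors(parents: dict[str, str], node: str) -> list[str]:
    """Oracle: iterated parent lookup, root first."""
    chain = []
    while node in parents:
        node = parents[node]
        chain.append(node)
    return chain[::-1]


def brute_force_closure(tax: hx.Taxonomy) -> set[tuple[str, str, int]]:
    """Oracle: enumerate every (ancestor-or-self, node, distance) pair by
    walking parent pointers, independent of the closure encoder."""
    parents = parent_map(tax)
    pairs = set()
    for n in tax.node_ids:
        chain = [n] + walk_ancestors(parents, n)[::-1]  # self → root
        for d, a in enumerate(chain):
            pairs.add((a, n, d))
    return pairs
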