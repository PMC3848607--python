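"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

import recurra as r


@pytest.fixture
def cherry_tree():
    """The worked 3-leaf example tree: ((x:1,y:1):1,z:2);"""
    return r.parse_newick("((x:1,y:1):1,z:2);")


@pytest.fixture
def small_cohort():
    """One deterministic synthetic cohort at default planted effects."""
    cfg = r.CohortSimConfig()
    tree = r.simulate_tree(cfg.n_taxa, np.random.default_rng(101))
    table, meta = r.simulate_cohort(cfg, tree, np.random.default_rng(202))
    return cfg, tree, table, meta


def random_tree_and_samples(seed, max_leaves=12, max_count=10):
    """Random (tree, countsA, countsB) instance for metric property tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_leaves + 1))
    tree = r.simulate_tree(n, rng)
    leaves = tree.leaf_names
    while True:
        a = {t: int(rng.integers(0, max_count + 1)) for t in leaves}
        b = {t: int(rng.integers(0, max_count + 1)) for t in leaves}
        if sum(a.values()) > 0 and sum(b.values()) > 0:
            return tree, a, b


def brute_force_unifrac(tree, counts_a, counts_b, normalized):
    """Independent weighted UniFrac by per-branch leaf-set enumeration.

    Walks the raw tree nodes, enumerating the descendant leaf set of
    every branch, with no shared code with the package implementation.
    """
    root = tree.root
    tot_a = float(sum(max(c, 0) for c in counts_a.values()))
    tot_b = float(sum(max(c, 0) for c in counts_b.values()))
    raw = 0.0
    for node in root.traverse(include_self=False):
        if node.is_tip():
            leaves = {node.name}
        else:
            leaves = {t.name for t in node.tips()}
        pa = sum(counts_a.get(l, 0) for l in leaves) / tot_a
        pb = sum(counts_b.get(l, 0) for l in leaves) / tot_b
        raw += node.length * abs(pa - pb)
    if not normalized:
        return raw
    denom = 0.0
    for tip in root.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length
            node = node.parent
        pa = counts_a.get(tip.name, 0) / tot_a
        pb = counts_b.get(tip.name, 0) / tot_b
        denom += depth * (pa + pb)
    return raw / denom if denom else 0.0
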