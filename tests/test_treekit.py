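"""Tree I/O, NJ inference, comparison and pruning."""

import itertools
import random

import numpy as np
import pytest

from polyorigin import treekit as tk
from polyorigin._coalescent import LNode, Population, simulate_populations
import math


def test_newick_round_trip():
    text = "((A:1,B:1):1,C:2);"
    assert tk.write_newick(tk.read_newick(text)) == text


def test_newick_support_values_preserved():
    text = "((A,B)0.97,C);"
    tree = tk.read_newick(text)
    supports = [tk.node_support(n) for n in tree.preorder_node_iter()
                if not n.is_leaf()]
    assert 0.97 in supports
    assert tk.write_newick(tree) == text


def test_newick_parse_error_reports_position():
    with pytest.raises(tk.NewickParseError, match="column"):
        tk.read_newick("((A:1,B:1:1,C:2);")


def _ls_fit(labels, D, topology):
    """Least-squares edge fit error for a 4-taxon unrooted topology."""
    (a, b), (c, d) = topology
    pairs = list(itertools.combinations(range(4), 2))
    # columns: terminal edges 0-3 + internal edge
    X = np.zeros((len(pairs), 5))
    y = np.zeros(len(pairs))
    sides = {a: 0, b: 0, c: 1, d: 1}
    for r, (i, j) in enumerate(pairs):
        X[r, i] = X[r, j] = 1
        if sides[labels[i]] != sides[labels[j]]:
            X[r, 4] = 1
        y[r] = D[i, j]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((X @ coef - y) ** 2).sum())


def test_nj_recovers_additive_topology():
    """NJ matches the exhaustive least-squares oracle on additive data."""
    # tree ((A:1,B:2):1.5,(C:3,D:1)) -> additive distances
    labels = ["A", "B", "C", "D"]
    D = np.array([
        [0, 3, 5.5, 3.5],
        [3, 0, 6.5, 4.5],
        [5.5, 6.5, 0, 4.0],
        [3.5, 4.5, 4.0, 0],
    ])
    topologies = [
        (("A", "B"), ("C", "D")),
        (("A", "C"), ("B", "D")),
        (("A", "D"), ("B", "C")),
    ]
    fits = {t: _ls_fit(labels, D, t) for t in topologies}
    best = min(fits, key=fits.get)
    assert best == (("A", "B"), ("C", "D")) and fits[best] < 1e-20

    light = tk._neighbor_joining(labels, D)
    bips = {frozenset(s) for s in tk.bipartitions(light)}
    assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips


def test_nj_identical_sequences_zero_lengths():
    aln = {x: "ACGTACGTAC" for x in "ABCD"}
    tree = tk.infer_gene_tree(aln)
    assert all((e.length or 0.0) == 0.0 for e in tree.preorder_edge_iter())


def test_infer_gene_tree_needs_three_sequences():
    with pytest.raises(ValueError):
        tk.infer_gene_tree({"A": "ACGT", "B": "ACGT"})


def test_outgroup_rooting():
    aln = {
        "A": "AAAAAAAAAAAA",
        "B": "AAAAAAAAAATT",
        "C": "TTTTTTAAAAAA",
        "D": "TTTTTTTTTTTT",
    }
    tree = tk.infer_gene_tree(aln, outgroup="D")
    root_children = tree.seed_node.child_nodes()
    out_sides = [
        {l.taxon.label for l in c.leaf_iter()} for c in root_children
    ]
    assert {"D"} in out_sides


def test_hky_distance_increases_with_divergence_and_saturation_fallback():
    x = np.array([0, 1, 2, 3] * 25, dtype=np.int8)
    y = x.copy()
    y[:10] = (y[:10] + 1) % 4
    d_small, fell_small = tk.hky_corrected_distance(x, y)
    assert not fell_small and d_small > 0.1  # corrected above p-distance
    rng = np.random.default_rng(0)
    z = rng.integers(0, 4, size=100).astype(np.int8)
    d_sat, _ = tk.hky_corrected_distance(x, z)
    assert d_sat > d_small


def test_bootstrap_clean_clade_full_support_and_seed_stable():
    aln = {
        "A": "A" * 30 + "C" * 30,
        "B": "A" * 30 + "C" * 30,
        "C": "T" * 30 + "G" * 30,
        "D": "T" * 30 + "G" * 30,
        "E": "T" * 30 + "C" * 30,
    }
    t1 = tk.bootstrap_support(aln, n_reps=50, seed=5)
    t2 = tk.bootstrap_support(aln, n_reps=50, seed=5)
    assert tk.write_newick(t1) == tk.write_newick(t2)
    # the A|B vs C|D|E bipartition may be carried by either side's node
    supports = {}
    for n in t1.preorder_node_iter():
        if n.is_leaf() or n is t1.seed_node:
            continue
        side = frozenset(l.taxon.label for l in n.leaf_iter())
        key = min(side, frozenset("ABCDE") - side, key=sorted)
        supports[key] = tk.node_support(n)
    assert supports.get(frozenset("AB")) == 1.0
    with pytest.raises(ValueError):
        tk.bootstrap_support(aln, n_reps=0, seed=1)


def test_rf_examples():
    t = tk.read_newick("((A,B),(C,D),E);")
    assert tk.rf_distance(t, tk.read_newick("((A,B),(C,D),E);")) == 0
    # one NNI: swap B and C
    assert tk.rf_distance(t, tk.read_newick("((A,C),(B,D),E);")) == 4
    nni = tk.read_newick("(((A,C),B),(D,E));")  # single NNI from ((A,B),C)
    base = tk.read_newick("(((A,B),C),(D,E));")
    assert tk.rf_distance(base, nni) == 2
    # two caterpillars with no shared split: maximal distance 2(n-3)
    cat = tk.read_newick("(((((A,B),C),D),E),F);")
    far = tk.read_newick("(((((A,C),E),B),F),D);")
    assert tk.rf_distance(cat, far) == 2 * (6 - 3)


def test_rf_is_a_metric_on_random_trees():
    rng = random.Random(9)

    def rand_tree():
        pops = [Population(pid=0, t0=0.0, t1=math.inf, ne=10.0)]
        entry = {0: [LNode(label=f"x{i}") for i in range(7)]}
        light = simulate_populations(pops, entry, 1.0, rng)
        from polyorigin._coalescent import newick_of

        return tk.read_newick(newick_of(light))

    trees = [rand_tree() for _ in range(6)]
    for a, b in itertools.combinations(trees, 2):
        assert tk.rf_distance(a, b) == tk.rf_distance(b, a)
        assert tk.rf_distance(a, a) == 0
    for a, b, c in itertools.combinations(trees, 3):
        assert (
            tk.rf_distance(a, c)
            <= tk.rf_distance(a, b) + tk.rf_distance(b, c)
        )


def test_rf_restricts_to_shared_taxa():
    t1 = tk.read_newick("((A:1,B:1):1,((C:1,D:1):1,X:2):1);")
    t2 = tk.read_newick("((A:1,B:1):1,((C:1,D:1):1,Y:2):1);")
    assert tk.rf_distance(t1, t2) == 0
    with pytest.raises(ValueError):
        tk.rf_distance(
            tk.read_newick("((A,B),C);"), tk.read_newick("((A,B),D);")
        )


def test_prune_sums_branch_lengths_and_composes():
    tree = tk.read_newick("((A:1,B:2):3,C:4);")
    pruned = tk.prune(tree, ["B"])
    tips = {l.taxon.label: l for l in pruned.leaf_node_iter()}
    assert set(tips) == {"A", "C"}
    assert tips["A"].edge.length == pytest.approx(4.0)  # 1 + 3 merged
    t6 = tk.read_newick("(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);")
    once = tk.prune(tk.prune(t6, ["A"]), ["C"])
    both = tk.prune(t6, ["A", "C"])
    assert tk.rf_distance(once, both) == 0
    assert tk.branch_score_distance(once, both) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        tk.prune(t6, ["Z"])
    with pytest.raises(ValueError):
        tk.prune(t6, list("ABCDEF"))


def test_prune_preserves_ultrametricity():
    tree = tk.read_newick("((A:1,B:1):2,(C:2,D:2):1);")
    pruned = tk.prune(tree, ["B"])
    light = tk.to_light(pruned)
    assert all(abs(l.age) < 1e-9 for l in light.leaves())


def test_branch_score_distance_identical_and_shifted():
    t1 = tk.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert tk.branch_score_distance(t1, t1) == 0.0
    # unrooted, the two root edges merge into one internal edge: 2 vs 4
    t2 = tk.read_newick("((A:1,B:1):2,(C:1,D:1):2);")
    assert tk.branch_score_distance(t1, t2) == pytest.approx(2.0, rel=1e-9)
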