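"""Homoeologue clade detection, pattern calls and the hybridization test."""

import numpy as np
import pytest

from polyorigin import origin as og
from polyorigin import phasing as ph
from polyorigin import synthetic_data as sd
from polyorigin import treekit as tk

# archetypal gene trees: tetraploid alleles T|*, diploids D*
NONSISTER = (  # ultrametric: every tip at depth 4
    "(((T|1|a1:1,T|1|a2:1)0.99:1,(D1|1|h1:1,D1|1|h2:1)0.99:1)0.98:2,"
    "(((T|1|a3:1,T|1|a4:1)0.99:1,(D2|1|h1:1,D2|1|h2:1)0.95:1)0.97:1,"
    "(D3|1|h1:2,D3|1|h2:2)0.9:1)0.96:1);"
)
MONOPHYLETIC = (
    "(((T|1|a1:1,T|1|a2:1)0.99:1,(T|1|a3:1,T|1|a4:1)0.99:1)0.98:2,"
    "((D1|1|h1:2,D2|1|h1:2)0.9:1,D3|1|h1:3)0.9:1);"
)
STRAGGLER = (
    "((((T|1|a1:1,T|1|a2:1)0.99:1,D1|1|h1:2)0.95:1,"
    "((T|1|a3:1,D2|1|h1:1)0.99:1,(T|1|a4:1,D3|1|h1:1)0.9:1)0.9:1)0.9:1,"
    "D4|1|h1:4);"
)


def test_non_sister_clades_detected():
    clades = og.find_homoeologue_clades(tk.read_newick(NONSISTER), {"T"})
    assert sorted(clades.clade_a) == ["T|1|a1", "T|1|a2"]
    assert sorted(clades.clade_b) == ["T|1|a3", "T|1|a4"]
    assert not clades.sister
    assert clades.separating_supported_nodes >= 1
    assert not clades.unplaced
    assert og.classify_pattern(clades).pattern == og.ALLO_LIKE


def test_monophyletic_tetraploids_are_sister_subclades():
    clades = og.find_homoeologue_clades(tk.read_newick(MONOPHYLETIC), {"T"})
    assert clades.sister
    assert og.classify_pattern(clades).pattern == og.AUTO_LIKE


def test_straggler_alleles_unplaced():
    clades = og.find_homoeologue_clades(tk.read_newick(STRAGGLER), {"T"})
    assert clades.unplaced  # a3/a4 group with diploids, not with each other
    assert og.classify_pattern(clades).pattern == og.INCOMPLETE_FIXATION


def test_low_support_separation_is_unresolved():
    text = NONSISTER.replace("0.98", "0.5").replace("0.97", "0.4").replace(
        "0.96", "0.3"
    )
    clades = og.find_homoeologue_clades(tk.read_newick(text), {"T"},
                                        min_support=0.9)
    assert not clades.sister
    assert clades.separating_supported_nodes == 0
    assert og.classify_pattern(clades).pattern == og.UNRESOLVED


def test_no_tetraploid_tips_errors():
    with pytest.raises(ValueError):
        og.find_homoeologue_clades(
            tk.read_newick("((D1|1|h1,D1|1|h2),D2|1|h1);"), {"T"}
        )


def test_build_test_trees_share_diploids_and_relabel():
    tree = tk.read_newick(NONSISTER)
    clades = og.find_homoeologue_clades(tree, {"T"})
    ta, tb = og.build_test_trees(tree, clades)
    dip = lambda t: sorted(
        l.taxon.label for l in t.leaf_node_iter()
        if not l.taxon.label.startswith(og.PLACEHOLDER)
    )
    assert dip(ta) == dip(tb)
    ph_a = [l.taxon.label for l in ta.leaf_node_iter()
            if l.taxon.label.startswith(og.PLACEHOLDER)]
    assert sorted(ph_a) == ["homoeologue|1", "homoeologue|2"]
    with pytest.raises(ValueError):
        og.build_test_trees(
            tree,
            og.HomoeologueClades("g", clades.clade_a, [], True, 0, [], True),
        )


def test_identical_test_trees_give_p_one():
    tree = tk.read_newick(NONSISTER)
    clades = og.find_homoeologue_clades(tree, {"T"})
    ta, _ = og.build_test_trees(tree, clades)
    res = og.ils_hybridization_test(ta, ta, ne_gene_copies=1000,
                                    gen_time=1.0, n_sims=50, seed=1)
    assert res.d_obs == 0.0 and res.rf_obs == 0
    assert res.p_value == 1.0


def test_p_value_is_always_positive(allo_truths):
    cfg, truths = allo_truths
    t = truths[0]
    clades = og.find_homoeologue_clades(t.tree(), {"T"})
    ta, tb = og.build_test_trees(t.tree(), clades)
    res = og.ils_hybridization_test(ta, tb, n_sims=100, seed=2)
    assert 0 < res.p_value <= 1
    assert res.p_value >= 1 / 101


def test_non_ultrametric_test_tree_rejected():
    ta = tk.read_newick("((homoeologue|1:1,homoeologue|2:1):1,"
                        "(D1:5,(D2:1,D3:1):1):1);")
    with pytest.raises(ValueError, match="ultrametric"):
        og.ils_hybridization_test(ta, ta, n_sims=10, seed=0)


def test_null_p_values_super_uniform_under_exchangeability(allo_truths):
    """Exchangeable draws never reject more often than nominal."""
    cfg, truths = allo_truths
    t = truths[1]
    clades = og.find_homoeologue_clades(t.tree(), {"T"})
    ta, tb = og.build_test_trees(t.tree(), clades)
    null = og.simulate_ils_null(ta, tb, cfg.ne_gene_copies,
                                cfg.generation_time, 2000, seed=3)
    ps = []
    block = 20  # 100 pseudo-observations, each vs 19 null draws
    for i in range(0, len(null), block):
        d_star, rest = null[i], null[i + 1 : i + block]
        ps.append((1 + sum(1 for x in rest if x >= d_star)) / (1 + len(rest)))
    ps = np.asarray(ps)
    for alpha in (0.05, 0.1, 0.25, 0.5):
        assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(
            alpha * (1 - alpha) / len(ps)
        )


def test_classifier_accuracy_on_truth_trees(allo_truths):
    cfg, truths = allo_truths
    calls = [
        og.classify_pattern(
            og.find_homoeologue_clades(t.tree(), {"T"})
        ).pattern
        for t in truths
    ]
    assert calls.count(og.ALLO_LIKE) >= 0.9 * len(calls)


# ---------------------------------------------------------------------------
# phased vs consensus, pseudo-diploid export


def test_homozygous_locus_consensus_equals_phased():
    """With no heterozygosity, phased and consensus trees coincide."""
    rng = np.random.default_rng(4)
    seqs = {}
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
    for k, nmut in (("A", 0), ("B", 12), ("C", 30), ("D", 60)):
        s = list(base)
        for pos in range(0, nmut * 13, 13):
            s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
        seqs[k] = "".join(s)
    pileups, phased = {}, {}
    for k, s in seqs.items():
        ind = f"{k}|1"
        pileup, _ = sd.simulate_reads({f"{ind}|h1": s, f"{ind}|h2": s},
                                      40, 100, 300, 30, 0.0, seed=5,
                                      locus=f"g1:{ind}")
        pileups[ind] = pileup
        phased[f"{ind}|a1"] = s
    records = og.compare_phased_vs_consensus(
        {"g1": phased}, {"g1": pileups}, tetraploid_labels=("A",)
    )
    rec = records[0]
    assert rec["consensus_monophyletic"] in (True, False)
    # consensus sequences equal the true (homozygous) sequences
    cons = {i: ph.majority_consensus(p) for i, p in pileups.items()}
    assert cons == {f"{k}|1": s for k, s in seqs.items()}


def test_export_pseudodiploids_bookkeeping():
    pset = ph.PhasedAlleleSet(
        individual="T|1", locus="g1",
        alleles={f"a{i}": "ACGT" for i in range(1, 5)},
        support={f"a{i}": [] for i in range(1, 5)},
    )
    clades = og.HomoeologueClades(
        gene="g1",
        clade_a=["T|1|a1", "T|1|a2"],
        clade_b=["T|1|a3", "T|1|a4"],
        sister=False, separating_supported_nodes=2,
        unplaced=[], species_coverage_ok=True,
    )
    table = og.export_pseudodiploids([pset], {"g1": clades})
    by = table.set_index(["pseudo_individual", "homoeologue"])["allele"]
    assert by[("T|1_1", "A")] == "a1" and by[("T|1_2", "A")] == "a2"
    assert by[("T|1_1", "B")] == "a3" and by[("T|1_2", "B")] == "a4"
    assert (table["flag"] == "").all()


def test_export_flags_two_allele_and_unassignable_cases():
    pset = ph.PhasedAlleleSet(
        individual="T|1", locus="g1",
        alleles={"a1": "ACGT", "a2": "ACGT", "a3": "ACGT"},
        support={k: [] for k in ("a1", "a2", "a3")},
    )
    clades = og.HomoeologueClades(
        gene="g1", clade_a=["T|1|a1"], clade_b=["T|1|a2"],
        sister=False, separating_supported_nodes=1,
        unplaced=["T|1|a3"], species_coverage_ok=True,
    )
    table = og.export_pseudodiploids([pset], {"g1": clades})
    assert (table["flag"] == "allele_reused").sum() == 2  # one per homoeologue
    assert (table["flag"] == "unassignable").sum() == 1


def test_compare_reports_bootstrap_supports(allo_dataset):
    """With n_boot set, placement supports appear in the records."""
    from polyorigin import phasing as phh

    loc = allo_dataset.loci[0]
    aln = {}
    for ind, pileup in loc.pileups.items():
        sites = phh.call_het_sites(pileup)
        part = phh.partition_reads(pileup, sites, seed=1)
        pas = phh.extend_to_tetraploid(pileup, part, individual=ind, seed=1)
        for aid, seq in pas.alleles.items():
            aln[f"{ind}|{aid}"] = seq
    records = og.compare_phased_vs_consensus(
        {loc.truth.locus: aln}, {loc.truth.locus: loc.pileups},
        n_boot=20, seed=3,
    )
    rec = records[0]
    assert "support_phased_a" in rec and "support_consensus_group" in rec
    if rec["support_phased_a"] is not None:
        assert 0.0 <= rec["support_phased_a"] <= 1.0
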