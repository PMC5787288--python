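"""Scenario construction, sequence evolution and read simulation."""

import math
import random

import numpy as np
import pytest
from scipy import linalg, stats

from polyorigin import synthetic_data as sd
from polyorigin._coalescent import LNode, SNode


# ---------------------------------------------------------------------------
# build_scenario


def test_allo_network_has_one_reticulation():
    cfg = sd.ScenarioConfig(scenario=sd.ALLO, n_diploid_species=5)
    net = sd.build_scenario(cfg)
    assert net.n_reticulations == 1
    assert set(net.tips) == {f"D{i}" for i in range(1, 6)} | {"T"}


def test_auto_network_has_no_reticulation():
    cfg = sd.ScenarioConfig(scenario=sd.AUTO)
    net = sd.build_scenario(cfg)
    assert net.n_reticulations == 0
    assert net.doubling is not None


def test_node_ages_match_calibrations():
    cfg = sd.ScenarioConfig(crown_age=11e6, calib_split=6.14e6)
    net = sd.build_scenario(cfg)
    assert max(net.node_ages) == 11e6
    assert 6.14e6 in net.node_ages
    assert cfg.polyploidy_time in net.node_ages


def test_segmental_requires_fraction():
    cfg = sd.ScenarioConfig(scenario=sd.SEGMENTAL)
    with pytest.raises(sd.ConfigError):
        sd.build_scenario(cfg)


def test_unknown_parent_rejected():
    cfg = sd.ScenarioConfig(hybrid_parents=("D1", "D99"))
    with pytest.raises(sd.ConfigError):
        sd.build_scenario(cfg)


def test_parents_merging_before_polyploidy_rejected():
    # D7 and D8 split very recently; a hybridization long before that
    # cannot have two distinct donors
    cfg = sd.ScenarioConfig(hybrid_parents=("D7", "D8"), polyploidy_time=5e6)
    with pytest.raises(sd.ConfigError, match="distinct"):
        sd.build_scenario(cfg)


# ---------------------------------------------------------------------------
# msc_simulate


def test_single_copy_single_tip():
    tree = sd.msc_simulate(SNode(label="X"), 100.0, {"X": 1}, seed=0,
                           as_light=True)
    assert tree.label == "X" and not tree.children


def test_segmental_mode_fractions():
    cfg = sd.ScenarioConfig(
        scenario=sd.SEGMENTAL, tetrasomic_fraction=0.2, n_loci=300,
        disomy_onset=1e6,
    )
    net = sd.build_scenario(cfg)
    truths = sd.simulate_gene_trees(net, cfg, rng=random.Random(3))
    frac = np.mean([t.mode == sd.TETRASOMIC_THEN_DISOMIC for t in truths])
    lo, hi = stats.binom.interval(0.999, 300, 0.2)
    assert lo / 300 <= frac <= hi / 300


def test_allo_subgenome_tags_and_auto_untagged():
    allo = sd.ScenarioConfig(n_loci=1, tetraploid_samples=1, seed=1)
    truths = sd.simulate_gene_trees(sd.build_scenario(allo), allo,
                                    rng=random.Random(1))
    assert sorted(set(truths[0].subgenome.values())) == ["A", "B"]
    auto = sd.ScenarioConfig(scenario=sd.AUTO, n_loci=1,
                             tetraploid_samples=1, seed=1)
    truths = sd.simulate_gene_trees(sd.build_scenario(auto), auto,
                                    rng=random.Random(1))
    assert set(truths[0].subgenome.values()) == {None}


# ---------------------------------------------------------------------------
# evolve_sequences


def _two_tip_tree(t_years):
    return LNode(age=t_years, children=[LNode(label="A"), LNode(label="B")])


def test_rate_zero_keeps_tips_identical():
    tree = _two_tip_tree(1e6)
    haps = sd.evolve_sequences(tree, 500, 3.0, (0.25,) * 4, None, 0.0, seed=0)
    assert haps["A"] == haps["B"]


def test_negative_rate_and_bad_shape_rejected():
    tree = _two_tip_tree(1e6)
    with pytest.raises(ValueError):
        sd.evolve_sequences(tree, 100, 3.0, (0.25,) * 4, None, -1e-9, seed=0)
    with pytest.raises(ValueError):
        sd.evolve_sequences(tree, 100, 3.0, (0.25,) * 4, 0.0, 1e-9, seed=0)


def test_hky_divergence_matches_matrix_exponential():
    """Observed differences match 1 - sum(pi_i P_ii(2t)) from scipy expm."""
    kappa, freqs, rate, t = 3.0, (0.3, 0.2, 0.2, 0.3), 1e-8, 5e6
    L = 50_000
    tree = _two_tip_tree(t)
    haps = sd.evolve_sequences(tree, L, kappa, freqs, None, rate, seed=11)
    p_obs = np.mean([a != b for a, b in zip(haps["A"], haps["B"])])
    # independent oracle: build Q here and use scipy's expm
    pi = np.array(freqs)
    Q = np.zeros((4, 4))
    ts_pairs = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = pi[j] * (kappa if (i, j) in ts_pairs else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()
    P = linalg.expm(Q * (2 * t * rate))
    p_exp = 1.0 - float((pi * np.diag(P)).sum())
    se = math.sqrt(p_exp * (1 - p_exp) / L)
    assert abs(p_obs - p_exp) < 3 * se


def test_large_kappa_suppresses_transversions():
    tree = _two_tip_tree(3e6)
    haps = sd.evolve_sequences(tree, 20_000, 1000.0, (0.25,) * 4, None,
                               1e-8, seed=3)
    ts_set = {frozenset("AG"), frozenset("CT")}
    ts = tv = 0
    for a, b in zip(haps["A"], haps["B"]):
        if a != b:
            if frozenset((a, b)) in ts_set:
                ts += 1
            else:
                tv += 1
    assert ts > 10 * max(tv, 1)


# ---------------------------------------------------------------------------
# simulate_reads


def test_read_depth_and_pair_count():
    haps = {"h1": "ACGT" * 643}  # 2572 bp
    depth, rl, ins = 60.0, 150, 500.0
    pileup, _ = sd.simulate_reads(haps, depth, rl, ins, 50.0, 0.0, seed=5)
    L = len(haps["h1"])
    cov = pileup.base_counts().sum(axis=1)
    assert cov.mean() == pytest.approx(depth, rel=0.10)
    # fragments are placed on a window one insert wider than the locus
    expected_pairs = depth * (L + ins - 1) / (2 * rl)
    n_pairs = len({r.id.rsplit("/", 1)[0] for r in pileup.reads})
    assert n_pairs == pytest.approx(expected_pairs, rel=0.05)


def test_error_free_reads_substring_match():
    rng = np.random.default_rng(1)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    pileup, rmap = sd.simulate_reads({"h": seq}, 30, 150, 400, 40, 0.0, seed=2)
    for r in pileup.reads:
        assert seq[r.start : r.start + len(r.seq)] == r.seq


def test_per_haplotype_counts_multinomially_balanced():
    haps = {f"h{i}": "A" * 2000 for i in range(4)}
    pileup, rmap = sd.simulate_reads(haps, 80, 150, 400, 40, 0.0, seed=7)
    pair_sources = {}
    for rid, hap in rmap.items():
        pair_sources[rid.rsplit("/", 1)[0]] = hap
    counts = [list(pair_sources.values()).count(f"h{i}") for i in range(4)]
    chi2, p = stats.chisquare(counts)
    assert p > 0.001


def test_insert_shorter_than_read_rejected():
    with pytest.raises(ValueError):
        sd.simulate_reads({"h": "A" * 1000}, 30, 150, 100, 10, 0.0, seed=0)


def test_pcr_duplicates_are_exact_copies():
    haps = {"h": "ACGT" * 500}
    pileup, rmap = sd.simulate_reads(
        haps, 30, 100, 300, 30, 0.0, seed=3, pcr_duplicate_rate=0.2
    )
    dups = [r for r in pileup.reads if "dup" in r.id]
    assert dups
    originals = {(r.start, r.seq) for r in pileup.reads if "dup" not in r.id}
    assert all((d.start, d.seq) in originals for d in dups)


# ---------------------------------------------------------------------------
# inject_recombinant


def test_inject_recombinant_boundaries_and_content():
    a, b = "A" * 10, "T" * 10
    assert sd.inject_recombinant(a, b, 5) == "AAAAATTTTT"
    assert sd.inject_recombinant(a, b, 9) == "A" * 9 + "T"
    with pytest.raises(ValueError):
        sd.inject_recombinant(a, b, 0)
    with pytest.raises(ValueError):
        sd.inject_recombinant(a, b + "T", 5)


# ---------------------------------------------------------------------------
# whole datasets


def test_dataset_ploidy_and_determinism():
    cfg = sd.ScenarioConfig(n_loci=2, n_diploid_species=3,
                            tetraploid_samples=2, seed=99)
    ds1 = sd.simulate_dataset(cfg)
    ds2 = sd.simulate_dataset(cfg)
    for l1, l2 in zip(ds1.loci, ds2.loci):
        assert l1.truth.haplotypes == l2.truth.haplotypes
        assert l1.truth.newick == l2.truth.newick
        for ind in l1.pileups:
            r1 = [(r.id, r.start, r.seq) for r in l1.pileups[ind].reads]
            r2 = [(r.id, r.start, r.seq) for r in l2.pileups[ind].reads]
            assert r1 == r2
    loc = ds1.loci[0]
    for ind in ds1.individuals:
        haps = [h for h in loc.truth.haplotypes if h.startswith(ind + "|")]
        assert len(haps) == (4 if ind.startswith("T|") else 2)
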