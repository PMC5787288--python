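"""Desk-scale reference experiments.

Each function runs one self-contained simulation experiment of the kind
used to validate the pipeline: coalescent-unit arithmetic, deep
coalescence probability, exact phasing recovery, Watterson-theta
recovery, ILS-test calibration and power, pattern classification, the
consensus-masking effect, and MaxChi performance.  They are used by the
test suite and by ``scripts/acceptance.py``; every stochastic experiment
takes an explicit seed and is reproducible.

Problem sizes are chosen so the full battery runs in a few minutes on one
CPU; the docstrings state each experiment's study conditions.
"""

from __future__ import annotations

import random

import numpy as np

from . import origin as og
from . import phasing as ph
from . import popgen
from . import recombination as rec
from . import synthetic_data as sd
from ._coalescent import SNode

__all__ = [
    "deep_coalescence_probability",
    "phasing_exact_recovery",
    "theta_recovery",
    "ils_calibration",
    "ils_power",
    "pattern_classification",
    "consensus_masking",
    "maxchi_injected_chimeras",
    "maxchi_clonal_false_positives",
]


# ---------------------------------------------------------------------------
# Coalescent arithmetic


def deep_coalescence_probability(seed: int = 0, n_reps: int = 10_000,
                                 t_cu: float | None = None,
                                 ne: float = 204_000.0,
                                 gen_time: float = 2.0) -> dict:
    """Analytic vs simulated probability of retained ancestral polymorphism.

    Two gene copies enter a branch of ``t_cu`` coalescent units (default:
    1 Ma at the study's Ne and generation time); the analytic survival
    probability exp(-t) is cross-checked against the fraction of
    ``n_reps`` coalescent simulations whose TMRCA exceeds the branch.
    """
    if t_cu is None:
        t_cu = popgen.coalescent_units(1e6, gen_time, ne)
    branch_years = t_cu * ne * gen_time
    guide = SNode(age=branch_years, children=[SNode(label="X", age=0.0)])
    rng = random.Random(seed)
    fail = 0
    for _ in range(n_reps):
        g = sd.msc_simulate(guide, ne, {"X": 2}, rng=rng,
                            generation_time=gen_time, as_light=True)
        if g.age > branch_years:
            fail += 1
    analytic = popgen.prob_retained_polymorphism(t_cu)
    mc_se = (analytic * (1 - analytic) / n_reps) ** 0.5
    return {
        "t_cu": t_cu,
        "analytic": analytic,
        "simulated": fail / n_reps,
        "mc_se": mc_se,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Phasing


def _phasing_config(seed: int) -> sd.ScenarioConfig:
    # one tetraploid against its two parental diploids; deep parental
    # divergence (crown split) gives dense subgenome-diagnostic sites
    return sd.ScenarioConfig(
        scenario=sd.ALLO,
        n_loci=1,
        n_diploid_species=2,
        tetraploid_samples=1,
        polyploidy_time=2e6,
        error_rate=0.0,
        seed=seed,
    )


def phasing_exact_recovery(seed: int = 0, n_loci: int = 20,
                           max_attempts: int = 400) -> dict:
    """Exact allele recovery on identifiable error-free tetraploid loci.

    Simulated ALLO loci (~2572 bp, 60x, error-free) are screened for the
    identifiability preconditions (every polymorphic state supported by
    >= 3 independent templates; adjacent informative sites bridged by read
    pairs; see ``exact_recovery_conditions_met``); the first ``n_loci``
    qualifying loci are phased and the recovered allele set compared with
    the distinct true haplotypes.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(max_attempts)]
    exact = 0
    used = 0
    attempts = 0
    for s in sub:
        if used >= n_loci:
            break
        attempts += 1
        ds = sd.simulate_dataset(_phasing_config(s))
        loc = ds.loci[0]
        pileup = loc.pileups["T|1"]
        if not sd.exact_recovery_conditions_met(loc.truth, pileup, "T|1"):
            continue
        used += 1
        sites = ph.call_het_sites(pileup)
        part = ph.partition_reads(pileup, sites, seed=s)
        pas = ph.extend_to_tetraploid(pileup, part, individual="T|1", seed=s)
        truth = {
            seq
            for hap, seq in loc.truth.haplotypes.items()
            if hap.startswith("T|1|")
        }
        if set(pas.alleles.values()) == truth:
            exact += 1
    if used < n_loci:
        raise RuntimeError(
            f"only {used} identifiable loci found in {attempts} attempts"
        )
    return {"n_loci": used, "exact": exact, "fraction": exact / used,
            "attempts": attempts}


# ---------------------------------------------------------------------------
# Watterson theta


def theta_recovery(seed: int = 0, n_loci: int = 500, n_samples: int = 6,
                   theta_true: float = 0.01, length: int = 2500,
                   mu_year: float = 3.611e-9, gen_time: float = 2.0) -> dict:
    """Estimator recovery on single-population coalescent loci.

    ``n_loci`` independent loci are simulated in one panmictic population
    whose size is set so that theta = 2 * N_gc * mu * g equals
    ``theta_true``; sequences evolve under HKY with homogeneous rates
    (isolating the estimator from rate-heterogeneity bias) and Watterson's
    theta is averaged across loci.
    """
    ne = theta_true / (2.0 * mu_year * gen_time)
    guide = SNode(label="X", age=0.0)
    rng = random.Random(seed)
    srng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    thetas = []
    for _ in range(n_loci):
        tree = sd.msc_simulate(guide, ne, {"X": n_samples}, rng=rng,
                               generation_time=gen_time, as_light=True)
        haps = sd.evolve_sequences(
            tree, length, hky_kappa=3.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
            gamma_shape=None, rate=mu_year, rng=srng,
        )
        thetas.append(popgen.watterson_theta(haps).theta_w)
    mean_theta = float(np.mean(thetas))
    ne_est = popgen.effective_size(mean_theta, mu_year, gen_time)
    return {
        "theta_true": theta_true,
        "theta_mean": mean_theta,
        "rel_err": mean_theta / theta_true - 1.0,
        "ne_true": ne,
        "ne_est": ne_est.ne_gene_copies,
        "ne_rel_err": ne_est.ne_gene_copies / ne - 1.0,
        "n_loci": n_loci,
    }


# ---------------------------------------------------------------------------
# ILS test


def _calibration_config(seed: int) -> sd.ScenarioConfig:
    # no hybridization: tetrasomic pools released, at the doubling time,
    # into the lineage with the shortest stem so ILS alone frequently
    # displaces the two homoeologue clades (the regime the test is for)
    return sd.ScenarioConfig(
        scenario=sd.AUTO,
        n_loci=1,
        n_diploid_species=8,
        hybrid_parents=("D8",),
        polyploidy_time=1e6,
        disomy_onset=1e6,
        tetraploid_samples=2,
        seed=seed,
    )


def _power_config(seed: int, n_loci: int) -> sd.ScenarioConfig:
    # deep hybridization: parents D1/D3 diverged ~9 Ma before the
    # polyploidy event (~22 coalescent units at Ne = 204,000, g = 2)
    return sd.ScenarioConfig(
        scenario=sd.ALLO,
        n_loci=n_loci,
        n_diploid_species=5,
        hybrid_parents=("D1", "D3"),
        polyploidy_time=2e6,
        tetraploid_samples=2,
        seed=seed,
    )


def _run_ils(truth: sd.LocusTruth, cfg: sd.ScenarioConfig, n_sims: int,
             seed: int):
    clades = og.find_homoeologue_clades(truth.tree(), {"T"}, gene=truth.locus)
    if not clades.clade_b or clades.unplaced:
        return None
    tree_a, tree_b = og.build_test_trees(truth.tree(), clades)
    return og.ils_hybridization_test(
        tree_a,
        tree_b,
        ne_gene_copies=cfg.ne_gene_copies,
        gen_time=cfg.generation_time,
        n_sims=n_sims,
        seed=seed,
        gene=truth.locus,
    )


def ils_calibration(seed: int = 0, n_replicates: int = 200,
                    n_sims: int = 500, alpha: float = 0.05) -> dict:
    """Type-I error of the hybridization test on ILS-only data.

    Gene trees are simulated under a no-hybridization scenario until
    ``n_replicates`` of them display two homoeologue clades; each is put
    through the full test and the rejection rate at ``alpha`` reported.
    """
    cfg = _calibration_config(seed)
    net = sd.build_scenario(cfg)
    rng = random.Random(seed)
    rejections = 0
    tested = 0
    i = 0
    while tested < n_replicates:
        i += 1
        if i > 20 * n_replicates:
            raise RuntimeError("calibration scenario yields too few test trees")
        truth = sd.simulate_gene_trees(net, cfg, rng=rng)[0]
        res = _run_ils(truth, cfg, n_sims, seed=seed * 100_000 + i)
        if res is None:
            continue
        tested += 1
        if res.p_value < alpha:
            rejections += 1
    return {
        "n_replicates": n_replicates,
        "rejections": rejections,
        "rate": rejections / n_replicates,
        "alpha": alpha,
        "n_sims": n_sims,
    }


def ils_power(seed: int = 0, n_replicates: int = 100, n_sims: int = 500,
              p_threshold: float = 0.01) -> dict:
    """Power of the hybridization test on deep-divergence ALLO loci."""
    cfg = _power_config(seed, 1)
    net = sd.build_scenario(cfg)
    rng = random.Random(seed)
    hits = 0
    tested = 0
    i = 0
    while tested < n_replicates:
        i += 1
        if i > 20 * n_replicates:
            raise RuntimeError("power scenario yields too few test trees")
        truth = sd.simulate_gene_trees(net, cfg, rng=rng)[0]
        res = _run_ils(truth, cfg, n_sims, seed=seed * 100_000 + i)
        if res is None:
            continue
        tested += 1
        if res.p_value < p_threshold:
            hits += 1
    return {
        "n_replicates": n_replicates,
        "significant": hits,
        "rate": hits / n_replicates,
        "p_threshold": p_threshold,
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# Pattern classification


def pattern_classification(seed: int = 0, n_loci: int = 200) -> dict:
    """Classifier accuracy on true gene trees from both scenario classes.

    ALLO: parental divergence ~22 coalescent units; AUTO: doubling 4 Ma
    ago (~10 units) with disomy restored 2.5 Ma ago, progenitor D1.
    """
    allo_cfg = _power_config(seed, n_loci)
    allo_net = sd.build_scenario(allo_cfg)
    allo_truths = sd.simulate_gene_trees(allo_net, allo_cfg,
                                         rng=random.Random(seed))
    auto_cfg = sd.ScenarioConfig(
        scenario=sd.AUTO,
        n_loci=n_loci,
        n_diploid_species=5,
        hybrid_parents=("D1",),
        polyploidy_time=4e6,
        disomy_onset=2.5e6,
        tetraploid_samples=2,
        seed=seed + 1,
    )
    auto_net = sd.build_scenario(auto_cfg)
    auto_truths = sd.simulate_gene_trees(auto_net, auto_cfg,
                                         rng=random.Random(seed + 1))

    def rate(truths, want):
        calls = [
            og.classify_pattern(
                og.find_homoeologue_clades(t.tree(), {"T"}, gene=t.locus)
            ).pattern
            for t in truths
        ]
        return sum(c == want for c in calls) / len(calls)

    return {
        "allo_like_rate": rate(allo_truths, og.ALLO_LIKE),
        "auto_like_rate": rate(auto_truths, og.AUTO_LIKE),
        "n_loci": n_loci,
    }


# ---------------------------------------------------------------------------
# Consensus masking


def consensus_masking(seed: int = 0, n_loci: int = 25) -> dict:
    """How often consensus sequences hide both homoeologue placements.

    ALLO loci (parents D1/D2, i.e. the deepest split) are phased per
    individual; gene trees are inferred from the phased alleles and from
    per-individual majority-consensus sequences.  Among loci where the
    phased tree recovers both true parental placements, the fraction
    where the consensus tree recovers *neither* is reported.
    """
    cfg = sd.ScenarioConfig(
        scenario=sd.ALLO,
        n_loci=n_loci,
        n_diploid_species=8,
        hybrid_parents=("D1", "D2"),
        polyploidy_time=2e6,
        tetraploid_samples=2,
        error_rate=0.0,
        seed=seed,
    )
    ds = sd.simulate_dataset(cfg)
    phased_alignments: dict[str, dict[str, str]] = {}
    pileups: dict[str, dict[str, ph.Pileup]] = {}
    for loc in ds.loci:
        aln: dict[str, str] = {}
        for ind, pileup in loc.pileups.items():
            sites = ph.call_het_sites(pileup)
            part = ph.partition_reads(pileup, sites, seed=cfg.seed)
            pas = ph.extend_to_tetraploid(
                pileup, part, individual=ind, seed=cfg.seed
            )
            for aid, seq in pas.alleles.items():
                aln[f"{ind}|{aid}"] = seq
        phased_alignments[loc.truth.locus] = aln
        pileups[loc.truth.locus] = loc.pileups
    records = og.compare_phased_vs_consensus(phased_alignments, pileups)
    parents = set(cfg.resolved_parents())
    both = 0
    neither = 0
    for recd in records:
        if recd.get("skipped"):
            continue
        pa, pb = set(recd["placement_a"]), set(recd["placement_b"])
        # require each placement to name a different true parent
        found_both = recd["phased_placements_found"] and (
            len((pa | pb) & parents) == 2 and pa & parents and pb & parents
        )
        if not found_both:
            continue
        both += 1
        cons = set(recd["consensus_sister"]) if recd["consensus_monophyletic"] else set()
        if not (cons & parents):
            neither += 1
    return {
        "n_loci": len(records),
        "phased_recovered_both": both,
        "consensus_recovered_neither": neither,
        "fraction_masked": neither / both if both else float("nan"),
    }


# ---------------------------------------------------------------------------
# MaxChi


def _two_parents(seed: int, length: int = 2500, divergence_years: float = 6e6,
                 rate: float = 3.611e-9):
    from ._coalescent import LNode

    tree = LNode(
        age=divergence_years,
        children=[LNode(label="P1", age=0.0), LNode(label="P2", age=0.0)],
    )
    rng = np.random.default_rng(seed)
    return sd.evolve_sequences(
        tree, length, hky_kappa=3.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
        gamma_shape=None, rate=rate, rng=rng,
    )


def maxchi_injected_chimeras(seed: int = 0, n_replicates: int = 30,
                             min_flank_sites: int = 20) -> dict:
    """Breakpoint detection accuracy on constructed chimeras.

    Each replicate evolves two parental sequences (~87 diagnostic sites
    over 2.5 kb), splices them at a random interior breakpoint with at
    least ``min_flank_sites`` diagnostic sites per flank, and screens the
    chimera against both parents.  Detection requires a confirmed event
    whose inferred breakpoint lies within +/-2 variable sites of truth.
    """
    rng = np.random.default_rng(seed)
    detected = 0
    within_two = 0
    for r in range(n_replicates):
        haps = _two_parents(int(rng.integers(2**31)))
        p1, p2 = haps["P1"], haps["P2"]
        diffs = [i for i, (a, b) in enumerate(zip(p1, p2)) if a != b]
        lo = diffs[min_flank_sites - 1] + 1
        hi = diffs[-min_flank_sites]
        bp = int(rng.integers(lo, hi + 1))
        chimera = sd.inject_recombinant(p1, p2, bp)
        aln = {"chimera": chimera, "P1": p1, "P2": p2}
        cands = rec.maxchi_scan(aln, p_screen=0.1, seed=int(rng.integers(2**31)),
                                n_perm=1000)
        confirmed = rec.confirm_events(
            aln, cands, p_confirm=0.01, n_perm=5000,
            seed=int(rng.integers(2**31)),
        )
        if not confirmed:
            continue
        detected += 1
        # truth breakpoint in variable-site rank space
        ranks = {pos: k for k, pos in enumerate(diffs)}
        truth_rank = sum(1 for d in diffs if d < bp)  # first right-flank site
        best = min(
            confirmed,
            key=lambda e: abs(
                sum(1 for d in diffs if d < e.breakpoint[1]) - truth_rank
            ),
        )
        est_rank = sum(1 for d in diffs if d < best.breakpoint[1])
        if abs(est_rank - truth_rank) <= 2:
            within_two += 1
    return {
        "n_replicates": n_replicates,
        "detected": detected,
        "breakpoint_within_2_sites": within_two,
        "detection_rate": detected / n_replicates,
        "accuracy_rate": within_two / n_replicates,
    }


def maxchi_clonal_false_positives(seed: int = 0, n_replicates: int = 200,
                                  n_samples: int = 6) -> dict:
    """Family-wise confirmed-event rate on recombination-free alignments."""
    guide = SNode(label="X", age=0.0)
    rng = random.Random(seed)
    srng = np.random.default_rng(np.random.SeedSequence(seed + 1).spawn(1)[0])
    fp = 0
    for r in range(n_replicates):
        tree = sd.msc_simulate(guide, 2_000_000, {"X": n_samples}, rng=rng,
                               generation_time=2.0, as_light=True)
        haps = sd.evolve_sequences(
            tree, 1500, hky_kappa=3.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
            gamma_shape=None, rate=3.611e-9, rng=srng,
        )
        cands = rec.maxchi_scan(haps, p_screen=0.1,
                                seed=int(srng.integers(2**31)), n_perm=500)
        if not cands:
            continue
        confirmed = rec.confirm_events(
            haps, cands, p_confirm=0.01, n_perm=5000,
            seed=int(srng.integers(2**31)),
        )
        if confirmed:
            fp += 1
    return {
        "n_replicates": n_replicates,
        "false_positive_families": fp,
        "rate": fp / n_replicates,
    }
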