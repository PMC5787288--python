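"""Het-site calling, read partitioning and tetraploid allele extension."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyorigin import phasing as ph
from polyorigin import synthetic_data as sd


def _pileup_from_columns(columns):
    """Reads realizing per-column base counts, each a distinct template.

    Trailing Ns vary the sequences so reads are not collapsed as PCR
    duplicates; N contributes nothing to any column.
    """
    reads = []
    k = 0
    max_n = 0
    for pos, counts in columns.items():
        for base, n in counts.items():
            max_n = max(max_n, n)
            for i in range(n):
                reads.append(ph.Read(f"r{k}", None, pos, base + "N" * i))
                k += 1
    length = max(columns) + max_n + 1
    return ph.Pileup("L", length, reads)


def test_het_site_called_on_balanced_column():
    pileup = _pileup_from_columns({5: {"A": 30, "T": 28}})
    sites = ph.call_het_sites(pileup)
    assert [h.position for h in sites] == [5]
    assert sites[0].counts == {"A": 30, "T": 28}


def test_low_support_minor_state_is_not_het():
    pileup = _pileup_from_columns({5: {"A": 58, "T": 2}})
    assert ph.call_het_sites(pileup, min_support=3) == []


def test_pcr_duplicates_collapse_to_single_support():
    reads = [ph.Read(f"a{i}", None, 0, "AAAA") for i in range(10)]
    # three byte-identical duplicates carrying the only T observations
    reads += [ph.Read(f"d{i}", None, 0, "ATAA") for i in range(3)]
    # (identical start, no mate, same sequence -> one template)
    pileup = ph.Pileup("L", 4, reads)
    assert ph.call_het_sites(pileup, min_support=3) == []
    # three independent T-carrying templates (distinct reads) do count
    reads3 = [ph.Read(f"a{i}", None, 0, "AAAA" + "N" * i) for i in range(10)]
    reads3 += [
        ph.Read("t0", None, 0, "ATAA"),
        ph.Read("t1", None, 1, "TAA"),
        ph.Read("t2", None, 1, "TA"),
    ]
    pileup3 = ph.Pileup("L", 14, reads3)
    sites = ph.call_het_sites(pileup3, min_support=3)
    assert [h.position for h in sites] == [1]


def test_min_support_validation_and_empty_pileup():
    pileup = _pileup_from_columns({0: {"A": 5}})
    with pytest.raises(ValueError):
        ph.call_het_sites(pileup, min_support=0)
    with pytest.raises(ValueError):
        ph.call_het_sites(ph.Pileup("L", 10, []))


def test_partition_recovers_diploid_truth():
    """Error-free diploid reads segregate exactly by haplotype."""
    rng = np.random.default_rng(0)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    h2 = list(base)
    for pos in range(50, 2000, 120):  # dense het sites
        h2[pos] = "A" if base[pos] != "A" else "G"
    haps = {"h1": base, "h2": "".join(h2)}
    pileup, rmap = sd.simulate_reads(haps, 40, 150, 450, 40, 0.0, seed=1)
    sites = ph.call_het_sites(pileup)
    assert sites
    part = ph.partition_reads(pileup, sites, seed=1)
    informative = [
        rid
        for grp in part.groups
        for rid in grp
        if rid not in set(part.randomly_assigned)
    ]
    for g, grp in enumerate(part.groups):
        sources = {rmap[rid] for rid in grp if rid in informative}
        assert len(sources) == 1
    assert {part.drafts[0], part.drafts[1]} == {haps["h1"], haps["h2"]}


def test_partition_without_het_sites_returns_single_group():
    pileup, _ = sd.simulate_reads({"h": "ACGT" * 300}, 30, 100, 300, 30, 0.0,
                                  seed=2)
    part = ph.partition_reads(pileup, [], seed=0)
    assert part.status == "no_het_sites"
    assert not part.groups[1]
    assert part.drafts[0] == "ACGT" * 300


def test_partition_deterministic_given_seed():
    haps = {"h1": "ACGT" * 500, "h2": "ACGA" * 500}
    pileup, _ = sd.simulate_reads(haps, 40, 150, 400, 40, 0.001, seed=3)
    sites = ph.call_het_sites(pileup)
    p1 = ph.partition_reads(pileup, sites, seed=9)
    p2 = ph.partition_reads(pileup, sites, seed=9)
    assert p1.groups == p2.groups and p1.drafts == p2.drafts


def test_extension_never_exceeds_two_alleles_for_diploids(allo_dataset):
    for loc in allo_dataset.loci:
        for ind, pileup in loc.pileups.items():
            if ind.startswith("T|"):
                continue
            sites = ph.call_het_sites(pileup)
            part = ph.partition_reads(pileup, sites, seed=4)
            pas = ph.extend_to_tetraploid(pileup, part, individual=ind, seed=4)
            assert 1 <= len(pas.alleles) <= 2


def test_extension_recovers_four_tetraploid_alleles():
    from polyorigin.experiments import _phasing_config

    ss = np.random.SeedSequence(12345)
    for sub in ss.spawn(200):
        s = int(sub.generate_state(1)[0] % 2**31)
        ds = sd.simulate_dataset(_phasing_config(s))
        loc = ds.loci[0]
        pileup = loc.pileups["T|1"]
        if not sd.exact_recovery_conditions_met(loc.truth, pileup, "T|1"):
            continue
        sites = ph.call_het_sites(pileup)
        part = ph.partition_reads(pileup, sites, seed=s)
        pas = ph.extend_to_tetraploid(pileup, part, individual="T|1", seed=s)
        truth = {
            seq
            for hap, seq in loc.truth.haplotypes.items()
            if hap.startswith("T|1|")
        }
        assert set(pas.alleles.values()) == truth
        return
    raise AssertionError("no identifiable locus found")


def test_phasing_never_invents_bases(allo_dataset):
    """Every non-N allele base is present in a supporting read there."""
    loc = allo_dataset.loci[0]
    pileup = loc.pileups["T|1"]
    sites = ph.call_het_sites(pileup)
    part = ph.partition_reads(pileup, sites, seed=5)
    pas = ph.extend_to_tetraploid(pileup, part, individual="T|1", seed=5)
    for aid, seq in pas.alleles.items():
        reads = [pileup.read(r) for r in pas.support[aid]]
        for col, base in enumerate(seq):
            if base == "N":
                continue
            assert any(
                r.start <= col < r.start + len(r.seq)
                and r.seq[col - r.start] == base
                for r in reads
            )


def test_over_ploid_contamination_flagged_without_fifth_allele():
    # a contaminant 5th haplotype puts three supported states at one column
    # inside one phased group (h1, h2, h5 share the group-defining base)
    def hap(muts):
        h = list("A" * 500)
        for pos, b in muts.items():
            h[pos] = b
        return "".join(h)

    haps = {
        "h1": hap({}),
        "h2": hap({300: "C"}),
        "h3": hap({100: "T"}),
        "h4": hap({100: "T"}),
        "h5": hap({300: "G"}),
    }
    pileup, _ = sd.simulate_reads(haps, 150, 100, 300, 30, 0.0, seed=6)
    sites = ph.call_het_sites(pileup)
    part = ph.partition_reads(pileup, sites, seed=6)
    pas = ph.extend_to_tetraploid(pileup, part, individual="x", seed=6)
    assert "over_ploid" in pas.flags
    assert len(pas.alleles) <= 4


# ---------------------------------------------------------------------------
# merge_contigs / majority_consensus


def test_merge_identical_overlap():
    assert ph.merge_contigs([(0, "ACGTACGTAC"), (8, "ACTTTT")]) == [
        (0, "ACGTACGTACTTTT")
    ]


def test_merge_gap_filled_with_ns():
    merged = ph.merge_contigs([(0, "AAAA"), (9, "TTTT")])
    assert merged == [(0, "AAAA" + "N" * 5 + "TTTT")]


def test_conflicting_overlap_kept_separate():
    out = ph.merge_contigs([(0, "AAAAAAAA"), (6, "TTTT")])
    assert out == [(0, "AAAAAAAA"), (6, "TTTT")]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 50), st.integers(5, 20)),
                min_size=1, max_size=6))
def test_merged_fragments_agree_with_reference(frags):
    """Fragments cut from one reference merge into reference substrings."""
    ref = ("ACGTTGCA" * 12)[:80]
    pieces = [(s, ref[s : s + l]) for s, l in frags if s < 80]
    pieces = [(s, p) for s, p in pieces if p]
    if not pieces:
        return
    for start, seq in ph.merge_contigs(pieces):
        for i, base in enumerate(seq):
            assert base == "N" or base == ref[start + i]


def test_majority_consensus_ties_and_gaps():
    pileup = _pileup_from_columns(
        {0: {"A": 30, "T": 28}, 1: {"A": 10, "T": 10}, 3: {"G": 4}}
    )
    assert ph.majority_consensus(pileup).startswith("AANG")


def test_pileup_tsv_round_trip(tmp_path):
    haps = {"h": "ACGT" * 100}
    pileup, _ = sd.simulate_reads(haps, 20, 50, 150, 20, 0.0, seed=8)
    path = tmp_path / "p.tsv"
    pileup.to_tsv(path)
    back = ph.Pileup.from_tsv(path, length=pileup.length)
    assert [(r.id, r.mate_id, r.start, r.seq) for r in back.reads] == [
        (r.id, r.mate_id, r.start, r.seq) for r in pileup.reads
    ]


def test_sam_adapter_reads_mapped_pairs(tmp_path):
    pytest.importorskip("pysam")
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:locus1\tLN:50\n"
        "p1\t99\tlocus1\t1\t60\t5M\t=\t11\t15\tACGTA\t*\n"
        "p1\t147\tlocus1\t11\t60\t5M\t=\t1\t-15\tGGGGG\t*\n"
        "clip\t0\tlocus1\t21\t60\t2S3M\t*\t0\t0\tNNACG\t*\n"
        "unmap\t4\t*\t0\t0\t*\t*\t0\t0\tACGTA\t*\n"
    )
    pileup = ph.Pileup.from_sam(sam)
    ids = sorted(r.id for r in pileup.reads)
    assert ids == ["p1/1", "p1/2"]  # clipped and unmapped reads excluded
    r1 = pileup.read("p1/1")
    assert r1.start == 0 and r1.seq == "ACGTA" and r1.mate_id == "p1/2"
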