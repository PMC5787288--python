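"""Read-backed phasing of up to four alleles per locus.

The workflow mirrors how polyploid alleles are recovered from short-read
data in practice: heterozygous sites are called from a per-locus pileup
(a polymorphic state must be supported by at least ``min_support``
independent reads, where PCR duplicates — reads identical in start, mate
start and sequence — count once); reads are then segregated into two
haplotype groups by agreement at the heterozygous sites they cover
(diploid-style phasing); and each group is re-examined for residual
polymorphism and split again, yielding one to four alleles per tetraploid
individual.  Reads covering no informative site are assigned
pseudo-randomly and flagged, since they cannot be placed on evidence.

Coordinates are 0-based, half-open throughout.  Reads are born aligned to
the locus coordinate system (simulation is gap-free); a SAM adapter is
provided for real mapped data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Read",
    "Pileup",
    "HetSite",
    "PartitionResult",
    "PhasedAlleleSet",
    "call_het_sites",
    "partition_reads",
    "extend_to_tetraploid",
    "merge_contigs",
    "majority_consensus",
]

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class Read:
    """One aligned read: ``seq`` spans [start, start+len(seq))."""

    id: str
    mate_id: str | None
    start: int
    seq: str


class Pileup:
    """A per-locus aligned read set with mate links."""

    def __init__(self, locus: str, length: int, reads: list[Read]):
        self.locus = locus
        self.length = int(length)
        self.reads = list(reads)
        for r in self.reads:
            if not (0 <= r.start and r.start + len(r.seq) <= self.length):
                raise ValueError(f"read {r.id} extends outside [0, {length})")
        self._by_id = {r.id: r for r in self.reads}
        self._codes: dict[str, np.ndarray] = {}

    def __len__(self):
        return len(self.reads)

    def read(self, read_id: str) -> Read:
        return self._by_id[read_id]

    def codes(self, read: Read) -> np.ndarray:
        """Read sequence as int8 codes (A,C,G,T -> 0..3, other -> -1)."""
        c = self._codes.get(read.id)
        if c is None:
            arr = np.frombuffer(read.seq.upper().encode(), dtype=np.uint8)
            c = np.full(arr.shape, -1, dtype=np.int8)
            for base, code in _B2I.items():
                c[arr == ord(base)] = code
            self._codes[read.id] = c
        return c

    def mate_start(self, read: Read) -> int | None:
        if read.mate_id is None:
            return None
        mate = self._by_id.get(read.mate_id)
        return None if mate is None else mate.start

    def unique_templates(self) -> list[Read]:
        """One representative per (start, mate start, sequence) class.

        Collapses PCR duplicates so that identical copies of one molecule
        cannot manufacture support for a variant.
        """
        seen = {}
        for r in self.reads:
            key = (r.start, self.mate_start(r), r.seq)
            if key not in seen:
                seen[key] = r
        return list(seen.values())

    def base_counts(self, reads=None) -> np.ndarray:
        """(length, 4) count matrix of A/C/G/T observations per column."""
        counts = np.zeros((self.length, 4), dtype=np.int32)
        for r in self.reads if reads is None else reads:
            c = self.codes(r)
            ok = c >= 0
            pos = np.arange(r.start, r.start + len(c))[ok]
            np.add.at(counts, (pos, c[ok].astype(np.intp)), 1)
        return counts

    # -- exchange formats ---------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tmate_id\tlocus\tstart\tseq\n")
            for r in self.reads:
                mate = r.mate_id if r.mate_id is not None else "."
                fh.write(f"{r.id}\t{mate}\t{self.locus}\t{r.start}\t{r.seq}\n")

    @classmethod
    def from_tsv(cls, path, length: int | None = None) -> "Pileup":
        reads, locus = [], None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["read_id", "mate_id"]:
                raise ValueError("not a pileup TSV (bad header)")
            for line in fh:
                rid, mate, loc, start, seq = line.rstrip("\n").split("\t")
                locus = loc
                reads.append(
                    Read(rid, None if mate == "." else mate, int(start), seq)
                )
        if length is None:
            length = max(r.start + len(r.seq) for r in reads)
        return cls(locus or "locus", length, reads)

    @classmethod
    def from_sam(cls, path, reference: str | None = None) -> "Pileup":
        """Adapter for mapped, paired SAM input (soft clips/indels excluded)."""
        import pysam

        reads = []
        length = None
        with pysam.AlignmentFile(str(path), "r") as sam:
            if reference is None:
                reference = sam.references[0]
            length = sam.get_reference_length(reference)
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped or aln.reference_name != reference:
                    continue
                if aln.cigartuples and any(op != 0 for op, _ in aln.cigartuples):
                    continue  # gap-free coordinate system only
                suffix = "/2" if aln.is_read2 else "/1"
                mate_suffix = "/1" if aln.is_read2 else "/2"
                rid = aln.query_name + suffix
                mate = aln.query_name + mate_suffix if aln.is_paired else None
                reads.append(
                    Read(rid, mate, aln.reference_start, aln.query_sequence)
                )
        return cls(reference, length, reads)


@dataclass
class HetSite:
    """An accepted heterozygous column."""

    position: int
    counts: dict[str, int]  # base -> independent-template support
    accepted: bool = True


@dataclass
class PartitionResult:
    """Outcome of the diploid-style read segregation."""

    groups: tuple[list[str], list[str]]  # read ids per group
    drafts: tuple[str, str]
    het_sites: list[HetSite]
    randomly_assigned: list[str] = field(default_factory=list)
    tie_conflicts: list[str] = field(default_factory=list)
    status: str = "ok"  # or "no_het_sites"


@dataclass
class PhasedAlleleSet:
    """1-4 phased allele sequences for one individual at one locus."""

    individual: str
    locus: str
    alleles: dict[str, str]  # allele id -> sequence (N allowed)
    support: dict[str, list[str]]  # allele id -> supporting read ids
    flags: set[str] = field(default_factory=set)
    decisions: list[str] = field(default_factory=list)  # audit trail

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fasta())

    def fasta(self) -> str:
        out = []
        for aid, seq in sorted(self.alleles.items()):
            out.append(f">{self.individual}|{self.locus}|{aid}\n{seq}\n")
        return "".join(out)


# ---------------------------------------------------------------------------
# Operations


def call_het_sites(pileup: Pileup, min_support: int = 3) -> list[HetSite]:
    """Columns with >= 2 base states each backed by ``min_support`` templates.

    Support is counted over PCR-deduplicated reads, so e.g. three identical
    duplicates of one molecule contribute a single observation.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(pileup) == 0:
        raise ValueError("empty pileup")
    counts = pileup.base_counts(pileup.unique_templates())
    n_supported = (counts >= min_support).sum(axis=1)
    out = []
    for pos in np.nonzero(n_supported >= 2)[0]:
        cc = counts[pos]
        bases = {
            _BASES[i]: int(cc[i]) for i in range(4) if cc[i] >= min_support
        }
        out.append(HetSite(position=int(pos), counts=bases))
    return out


def _fragments(pileup: Pileup):
    """Group reads into templates (mate pairs); returns list of read lists."""
    done = set()
    frags = []
    for r in pileup.reads:
        if r.id in done:
            continue
        members = [r]
        done.add(r.id)
        if r.mate_id is not None and r.mate_id in pileup._by_id:
            mate = pileup.read(r.mate_id)
            if mate.id not in done:
                members.append(mate)
                done.add(mate.id)
        frags.append(members)
    return frags


def _fragment_alleles(pileup, members, positions):
    """Bases a fragment carries at the given (sorted) het positions."""
    out = {}
    for r in members:
        c = pileup.codes(r)
        lo, hi = r.start, r.start + len(c)
        for pos in positions:
            if lo <= pos < hi:
                code = c[pos - lo]
                if code < 0:
                    continue
                base = _BASES[code]
                prev = out.get(pos)
                if prev is not None and prev != base:
                    out[pos] = None  # mates disagree: uninformative here
                else:
                    out[pos] = base
    return {p: b for p, b in out.items() if b is not None}


def _majority_draft(pileup, reads) -> str:
    counts = pileup.base_counts(reads)
    cov = counts.sum(axis=1)
    best = counts.argmax(axis=1)  # argmax takes lowest index on ties: A<C<G<T
    seq = np.where(cov > 0, best, 4)
    return "".join((_BASES + "N")[i] for i in seq)


def partition_reads(pileup: Pileup, het_sites, seed: int = 0,
                    _resolve_islands: bool = True) -> PartitionResult:
    """Segregate reads into two haplotype groups using heterozygous sites.

    Fragments (mate pairs) sharing het-site alleles are co-assigned; a
    fragment joining both groups' evidence is resolved by majority over the
    het sites it covers (ties broken pseudo-randomly by ``seed`` and
    flagged).  Fragments covering no informative site are segregated
    pseudo-randomly and flagged.  Draft sequences are per-group majority
    calls, ``N`` where a group has no coverage.
    """
    rng = random.Random(seed)
    if not het_sites:
        all_ids = [r.id for r in pileup.reads]
        draft = _majority_draft(pileup, pileup.reads)
        return PartitionResult(
            groups=(all_ids, []),
            drafts=(draft, ""),
            het_sites=[],
            status="no_het_sites",
        )
    positions = sorted(h.position for h in het_sites)
    frags = _fragments(pileup)
    frag_sites = [_fragment_alleles(pileup, m, positions) for m in frags]
    order = sorted(
        range(len(frags)),
        key=lambda i: (min(r.start for r in frags[i]), frags[i][0].id),
    )

    # seed the two groups from the most balanced well-supported het site:
    # a 50/50 split marks a site separating the two true groups, whereas a
    # skewed one (e.g. 3:1) may be polymorphism within one group
    by_pos = {h.position: h for h in het_sites}

    def seed_quality(p):
        counts = sorted(by_pos[p].counts.values(), reverse=True)
        total = sum(counts)
        return (counts[1] / total, total, -p)

    seed_pos = max(positions, key=seed_quality)
    top2 = sorted(
        by_pos[seed_pos].counts, key=lambda b: (-by_pos[seed_pos].counts[b], b)
    )[:2]
    b0, b1 = sorted(top2)

    assign: dict[int, int] = {}
    # profile[g][pos] = {base: count over assigned fragments}
    profile = ({}, {})

    def add_to(g, fi):
        assign[fi] = g
        for pos, base in frag_sites[fi].items():
            slot = profile[g].setdefault(pos, {})
            slot[base] = slot.get(base, 0) + 1

    for fi in order:
        base = frag_sites[fi].get(seed_pos)
        if base == b0:
            add_to(0, fi)
        elif base == b1:
            add_to(1, fi)

    import math as _math

    def score(fi):
        """Log-likelihood difference (group0 - group1) for a fragment.

        Per covered het site, the chance of the fragment's base under each
        group's observed base profile with add-half smoothing; keeping the
        full profile (not just the consensus) matters when a group is
        itself still polymorphic at a site, e.g. a rare allelic state must
        not be pushed toward the group that merely lacks it.
        """
        delta = 0.0
        informative = False
        for pos, base in frag_sites[fi].items():
            ll = []
            for g in (0, 1):
                slot = profile[g].get(pos, {})
                n = sum(slot.values())
                if n:
                    informative = True
                ll.append(_math.log((slot.get(base, 0) + 0.5) / (n + 1.0)))
            delta += ll[0] - ll[1]
        return delta if informative else None

    tie_conflicts: list[str] = []
    changed = True
    while changed:
        changed = False
        for fi in order:
            if fi in assign or not frag_sites[fi]:
                continue
            d = score(fi)
            if d is None or d == 0.0:
                continue
            add_to(0 if d > 0 else 1, fi)
            changed = True

    def refine():
        # re-score every fragment against the converged profiles,
        # repairing fragments mis-assigned before the profiles stabilized
        for _ in range(20):
            moved = False
            for fi in order:
                if fi not in assign or not frag_sites[fi]:
                    continue
                cur = assign[fi]
                for pos, base in frag_sites[fi].items():  # remove, re-score
                    slot = profile[cur][pos]
                    slot[base] -= 1
                    if slot[base] == 0:
                        del slot[base]
                d = score(fi)
                new = cur if d is None or d == 0.0 else (0 if d > 0 else 1)
                add_to(new, fi)
                if new != cur:
                    moved = True
            if not moved:
                break

    def detect_switch():
        """Boundary where the group phase is coherently inverted, if any.

        A switch error (both groups chimeric beyond some column) is a
        local optimum that single-fragment moves cannot leave: each
        fragment agrees with its block's majority.  It is betrayed by the
        fragments spanning the boundary, which match their own group on
        one side and the other group beyond it.  Returns the boundary (an
        index into ``positions``) with the most torn fragments, or None.
        """
        modal = []
        for g in (0, 1):
            m = {}
            for pos, slot in profile[g].items():
                if slot:
                    m[pos] = sorted(slot, key=lambda b: (-slot[b], b))[0]
            modal.append(m)
        pos_index = {p: i for i, p in enumerate(positions)}
        torn = [0] * (len(positions) + 1)
        spanning = [0] * (len(positions) + 1)
        for fi in order:
            sites = frag_sites[fi]
            if fi not in assign or len(sites) < 2:
                continue
            own, other = modal[assign[fi]], modal[1 - assign[fi]]
            covered = sorted(sites)
            agree = []
            for pos in covered:
                base = sites[pos]
                if base == own.get(pos) and base != other.get(pos):
                    agree.append(1)
                elif base == other.get(pos) and base != own.get(pos):
                    agree.append(-1)
                else:
                    agree.append(0)
            for j in range(1, len(covered)):
                left = sum(agree[:j])
                right = sum(agree[j:])
                u = pos_index[covered[j - 1]] + 1
                v = pos_index[covered[j]] + 1
                spanning[u] += 1
                spanning[v] -= 1
                if left * right < 0:
                    torn[u] += 1
                    torn[v] -= 1
        best_k, best = None, 0
        t = s = 0
        for k in range(1, len(positions)):
            t += torn[k]
            s += spanning[k]
            if t >= 3 and t * 2 > s and t > best:
                best_k, best = k, t
        return best_k

    refine()
    for _ in range(6):
        k = detect_switch()
        if k is None:
            break
        threshold = positions[k]
        for fi in order:
            sites = frag_sites[fi]
            if fi not in assign or not sites:
                continue
            if min(sites) >= threshold:
                cur = assign[fi]
                for pos, base in sites.items():
                    slot = profile[cur][pos]
                    slot[base] -= 1
                    if slot[base] == 0:
                        del slot[base]
                add_to(1 - cur, fi)
        refine()

    randomly_assigned: list[str] = []

    if _resolve_islands:
        # Het-site islands never reached by the profiles (no fragment links
        # them to the seeded block) are phased internally and attached to a
        # pseudo-random group as whole blocks: the phase BETWEEN blocks is
        # unknowable (a switching-error hazard), but scattering an island's
        # fragments one by one would fabricate within-group polymorphism.
        leftover = [fi for fi in order if fi not in assign and frag_sites[fi]]
        parent = {fi: fi for fi in leftover}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        by_site: dict[int, int] = {}
        for fi in leftover:
            for pos in frag_sites[fi]:
                if pos in by_site:
                    ra, rb = find(by_site[pos]), find(fi)
                    if ra != rb:
                        parent[ra] = rb
                else:
                    by_site[pos] = fi
        comps: dict[int, list[int]] = {}
        for fi in leftover:
            comps.setdefault(find(fi), []).append(fi)
        for root in sorted(comps, key=lambda r: min(comps[r])):
            members = comps[root]
            reads = [r for fi in members for r in frags[fi]]
            island = Pileup(pileup.locus, pileup.length, reads)
            island_positions = {
                pos for fi in members for pos in frag_sites[fi]
            }
            island_sites = [h for h in het_sites
                            if h.position in island_positions]
            sub = partition_reads(island, island_sites,
                                  seed=rng.randrange(2**31),
                                  _resolve_islands=False)
            flip = rng.randrange(2)
            ids_by_group = [set(ids) for ids in sub.groups]
            for fi in members:
                g = 0 if frags[fi][0].id in ids_by_group[0] else 1
                add_to(g ^ flip, fi)
                randomly_assigned.extend(r.id for r in frags[fi])

    for fi in order:
        if fi in assign:
            continue
        sites = frag_sites[fi]
        if sites:
            # covered het sites but evidence balanced: flag as tie
            tie_conflicts.extend(r.id for r in frags[fi])
        g = rng.randrange(2)
        add_to(g, fi)
        randomly_assigned.extend(r.id for r in frags[fi])

    group_reads = ([], [])
    for fi, g in assign.items():
        group_reads[g].extend(frags[fi])
    ids = tuple(sorted(r.id for r in grp) for grp in group_reads)
    drafts = tuple(_majority_draft(pileup, grp) for grp in group_reads)
    return PartitionResult(
        groups=ids,
        drafts=drafts,
        het_sites=list(het_sites),
        randomly_assigned=sorted(randomly_assigned),
        tie_conflicts=sorted(tie_conflicts),
    )


def extend_to_tetraploid(
    pileup: Pileup,
    partition: PartitionResult,
    min_support: int = 3,
    individual: str = "sample",
    seed: int = 0,
) -> PhasedAlleleSet:
    """Split each phased group again where it is internally polymorphic.

    Within each group, residual heterozygous sites (same independent-read
    support rule) indicate two allelic variants of that homoeologue; the
    group is re-partitioned and two allele sequences emitted.  A column
    with more than two supported states within one group is evidence of
    over-ploidy or contamination: the locus is flagged and no fifth allele
    is invented.
    """
    alleles: dict[str, str] = {}
    support: dict[str, list[str]] = {}
    flags: set[str] = set()
    decisions: list[str] = []
    if partition.randomly_assigned:
        flags.add("randomly_assigned_reads_present")
    k = 0
    for g, read_ids in enumerate(partition.groups):
        if not read_ids:
            continue
        sub = Pileup(pileup.locus, pileup.length, [pileup.read(i) for i in read_ids])
        sub_sites = call_het_sites(sub, min_support=min_support)
        counts = sub.base_counts(sub.unique_templates())
        if int(((counts >= min_support).sum(axis=1) >= 3).sum()) > 0:
            flags.add("over_ploid")
            flags.add("manual_review")
            decisions.append(f"group{g}: >2 supported states at some column")
        if not sub_sites:
            k += 1
            aid = f"a{k}"
            alleles[aid] = _majority_draft(sub, sub.reads)
            support[aid] = list(read_ids)
            decisions.append(f"group{g}: homogeneous -> single allele {aid}")
        else:
            subpart = partition_reads(sub, sub_sites, seed=seed * 4 + g + 1)
            if subpart.randomly_assigned:
                flags.add("randomly_assigned_reads_present")
            if subpart.tie_conflicts:
                flags.add("manual_review")
            for sg, sg_ids in enumerate(subpart.groups):
                if not sg_ids:
                    continue
                k += 1
                aid = f"a{k}"
                alleles[aid] = subpart.drafts[sg]
                support[aid] = list(sg_ids)
                decisions.append(
                    f"group{g}: split at "
                    f"{[h.position for h in sub_sites]} -> allele {aid}"
                )
    return PhasedAlleleSet(
        individual=individual,
        locus=pileup.locus,
        alleles=alleles,
        support=support,
        flags=flags,
        decisions=decisions,
    )


def merge_contigs(fragments: list[tuple[int, str]]) -> list[tuple[int, str]]:
    """Merge fragments sharing a coordinate system.

    Fragments whose overlap is identical (``N`` matches anything) are
    merged; non-overlapping fragments are joined with an ``N``-fill of the
    gap; overlapping-but-different fragments are kept separate.  Greedy
    left-to-right against the most recent merged fragment.
    """
    if not fragments:
        return []
    frags = sorted(fragments, key=lambda f: f[0])
    out = [frags[0]]
    for start, seq in frags[1:]:
        pstart, pseq = out[-1]
        pend = pstart + len(pseq)
        if start >= pend:
            out[-1] = (pstart, pseq + "N" * (start - pend) + seq)
            continue
        ov_p = pseq[start - pstart :]
        ov_n = seq[: len(ov_p)]
        n = min(len(ov_p), len(ov_n))
        compatible = all(
            a == b or a == "N" or b == "N" for a, b in zip(ov_p[:n], ov_n[:n])
        )
        if compatible:
            merged_ov = "".join(
                a if a != "N" else b for a, b in zip(ov_p[:n], ov_n[:n])
            )
            merged = pseq[: start - pstart] + merged_ov + seq[n:]
            if len(ov_p) > len(ov_n):  # incoming contained in previous
                merged = merged + pseq[start - pstart + n :]
            out[-1] = (pstart, merged)
        else:
            out.append((start, seq))
    return out


def majority_consensus(pileup: Pileup) -> str:
    """Per-column modal base; ties broken A<C<G<T; no coverage -> N."""
    if len(pileup) == 0:
        raise ValueError("empty pileup")
    return _majority_draft(pileup, pileup.reads)
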