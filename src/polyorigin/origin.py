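"""Inference of polyploid mode of origin from gene trees.

Given a gene tree containing up to four phased alleles per tetraploid
sample, the tetraploid tips fall into clades whose arrangement diagnoses
the origin: two clades separated by diploid lineages (each clade one
homoeologue) is the allopolyploid signature; a single clade of all
tetraploid alleles is the autopolyploid signature; tetraploid alleles
stranded among diploids indicate incomplete fixation under tetrasomic
inheritance.

Because incomplete lineage sorting can also displace clades, the
non-sister pattern is tested against a coalescent null: the two "test
trees" obtained by alternately pruning one homoeologue clade (keeping all
diploid alleles) are identical except for the tetraploid placement, and
their observed topological distance is compared with that of gene-tree
pairs simulated by pure ILS within each test tree treated as a species
tree (constant population size on all branches).  Rejection means the
homoeologue displacement exceeds what coalescent stochasticity explains.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import dendropy
import pandas as pd

from . import treekit
from ._coalescent import (
    LNode,
    Population,
    SNode,
    branch_score_light,
    simulate_populations,
)
from .phasing import PhasedAlleleSet, majority_consensus
from .synthetic_data import _snode_from_dendropy

__all__ = [
    "HomoeologueClades",
    "PatternCall",
    "IlsTestResult",
    "find_homoeologue_clades",
    "classify_pattern",
    "build_test_trees",
    "ils_hybridization_test",
    "compare_phased_vs_consensus",
    "export_pseudodiploids",
    "species_of",
]

ALLO_LIKE = "ALLO_LIKE"
AUTO_LIKE = "AUTO_LIKE"
INCOMPLETE_FIXATION = "INCOMPLETE_FIXATION"
UNRESOLVED = "UNRESOLVED"

PLACEHOLDER = "homoeologue"


def species_of(label: str) -> str:
    return label.split("|")[0]


@dataclass
class HomoeologueClades:
    gene: str
    clade_a: list[str]
    clade_b: list[str]
    sister: bool
    separating_supported_nodes: int
    unplaced: list[str]
    species_coverage_ok: bool


@dataclass
class PatternCall:
    pattern: str
    rationale: str


@dataclass
class IlsTestResult:
    gene: str
    d_obs: float  # branch-score distance between the test trees
    rf_obs: int  # RF distance, reported alongside
    null: list[float]
    n_sims: int
    ne_gene_copies: float
    seed: int | None
    p_value: float


def _supported(node, min_support: float) -> bool:
    s = treekit.node_support(node)
    return True if s is None else s >= min_support


def find_homoeologue_clades(
    tree: dendropy.Tree,
    tetraploid_labels,
    min_support: float = 0.9,
    gene: str = "gene",
) -> HomoeologueClades:
    """Locate the (up to two) maximal all-tetraploid clades in a gene tree.

    ``tetraploid_labels`` may list tetraploid species names or full tip
    labels.  When more than two maximal clades exist, the two largest are
    reported and the remaining tetraploid tips are unplaced; when the
    tetraploid alleles are monophyletic, the single clade's two daughter
    subclades are reported with ``sister=True``.
    """
    tetset = set(tetraploid_labels)

    def is_tetra(label):
        return label in tetset or species_of(label) in tetset

    leaves_of: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaves_of[node] = [node.taxon.label]
        else:
            leaves_of[node] = [
                x for c in node.child_nodes() for x in leaves_of[c]
            ]
    all_tetra = [l for l in leaves_of[tree.seed_node] if is_tetra(l)]
    if not all_tetra:
        raise ValueError("no tetraploid tips in tree")

    maximal = []
    for node in tree.postorder_node_iter():
        if not all(is_tetra(l) for l in leaves_of[node]):
            continue
        parent = node.parent_node
        if parent is None or not all(is_tetra(l) for l in leaves_of[parent]):
            maximal.append(node)

    if len(maximal) == 1:
        node = maximal[0]
        if node.is_leaf() or len(node.child_nodes()) < 2:
            return HomoeologueClades(
                gene=gene,
                clade_a=leaves_of[node],
                clade_b=[],
                sister=True,
                separating_supported_nodes=0,
                unplaced=[],
                species_coverage_ok=False,
            )
        kids = node.child_nodes()
        clade_a = leaves_of[kids[0]]
        clade_b = [x for k in kids[1:] for x in leaves_of[k]]
        root_a, root_b = kids[0], kids[1]
        sister = True
        sep = 0
    else:
        maximal.sort(key=lambda nd: (-len(leaves_of[nd]), min(leaves_of[nd])))
        root_a, root_b = maximal[0], maximal[1]
        clade_a, clade_b = leaves_of[root_a], leaves_of[root_b]
        unplaced = [x for nd in maximal[2:] for x in leaves_of[nd]]
        sister = root_a.parent_node is root_b.parent_node
        # nodes strictly between the clade roots, excluding their MRCA:
        # each one attaches a diploid lineage between the homoeologues
        anc_a = []
        p = root_a.parent_node
        while p is not None:
            anc_a.append(p)
            p = p.parent_node
        anc_b = []
        p = root_b.parent_node
        while p is not None and p not in anc_a:
            anc_b.append(p)
            p = p.parent_node
        mrca = p
        path = anc_a[: anc_a.index(mrca)] + anc_b if mrca is not None else anc_b
        sep = sum(1 for nd in path if _supported(nd, min_support))
        species = {species_of(l) for l in all_tetra}
        cov = all(
            species <= {species_of(l) for l in clade}
            for clade in (clade_a, clade_b)
        )
        return HomoeologueClades(
            gene=gene,
            clade_a=sorted(clade_a),
            clade_b=sorted(clade_b),
            sister=sister,
            separating_supported_nodes=sep,
            unplaced=sorted(unplaced),
            species_coverage_ok=cov,
        )

    species = {species_of(l) for l in all_tetra}
    cov = all(
        species <= {species_of(l) for l in clade}
        for clade in (clade_a, clade_b)
        if clade
    )
    return HomoeologueClades(
        gene=gene,
        clade_a=sorted(clade_a),
        clade_b=sorted(clade_b),
        sister=sister,
        separating_supported_nodes=sep,
        unplaced=[],
        species_coverage_ok=cov,
    )


def classify_pattern(clades: HomoeologueClades) -> PatternCall:
    """Call the polyploidy pattern a gene tree displays."""
    if clades.unplaced:
        return PatternCall(
            INCOMPLETE_FIXATION,
            f"tetraploid alleles {clades.unplaced} fall outside both "
            "homoeologue clades (incomplete fixation under tetrasomy)",
        )
    if not clades.clade_b:
        return PatternCall(UNRESOLVED, "fewer than two tetraploid subclades")
    if clades.sister:
        return PatternCall(
            AUTO_LIKE,
            "tetraploid alleles are monophyletic (two sister subclades)",
        )
    if clades.separating_supported_nodes >= 1:
        return PatternCall(
            ALLO_LIKE,
            f"two non-sister homoeologue clades separated by "
            f"{clades.separating_supported_nodes} supported node(s)",
        )
    return PatternCall(
        UNRESOLVED, "non-sister clades but no supported separating node"
    )


def build_test_trees(tree: dendropy.Tree, clades: HomoeologueClades):
    """Alternately pruned test trees sharing a relabelled tetraploid clade.

    ``tree_a`` retains clade A (clade B and unplaced tetraploid tips are
    pruned) and vice versa; all diploid tips are kept in both.  The
    retained clade's tips are renamed to a common placeholder series so
    the two trees share a taxon set differing only in where the
    homoeologue attaches.
    """
    if not clades.clade_a or not clades.clade_b:
        raise ValueError("need two homoeologue clades to build test trees")

    def one(keep, drop):
        pruned = treekit.prune(tree, list(drop) + list(clades.unplaced))
        # reparse so relabelling cannot touch the input tree's namespace
        out = treekit.read_newick(treekit.write_newick(pruned))
        mapping = {
            lab: f"{PLACEHOLDER}|{i + 1}" for i, lab in enumerate(sorted(keep))
        }
        for taxon in out.taxon_namespace:
            if taxon.label in mapping:
                taxon.label = mapping[taxon.label]
        return out

    tree_a = one(clades.clade_a, clades.clade_b)
    tree_b = one(clades.clade_b, clades.clade_a)
    return tree_a, tree_b


def ils_hybridization_test(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    ne_gene_copies: float = 204_000.0,
    gen_time: float = 2.0,
    n_sims: int = 1000,
    seed: int | None = None,
    gene: str = "gene",
) -> IlsTestResult:
    """Coalescent test of hybridization against an ILS-only null.

    The observed statistic is the branch-score distance between the two
    test trees (restricted to their shared taxa; the coarser RF count is
    reported alongside).  Under the null, the two
    homoeologue positions are alternative outcomes of incomplete lineage
    sorting from a *single* origin, so each null replicate re-enacts that
    process inside a test tree treated as the species history (constant
    ``ne_gene_copies`` on all branches): two parallel gene pools — kept
    apart below the homoeologue attachment, the way disomic inheritance
    isolates subgenomes — are released at the attachment point and
    coalesce through the shared diploid backbone; the replicate's
    statistic is the RF distance between the two single-pool restrictions
    of the resulting gene tree.  Sharing one backbone realization per
    replicate mirrors the observed statistic, whose two test trees are
    identical apart from the tetraploid placement.  Replicates alternate
    between the two test trees.  The p-value uses the add-one convention
    and is therefore always positive.
    """
    d_obs = treekit.branch_score_distance(tree_a, tree_b)
    rf_obs = treekit.rf_distance(tree_a, tree_b)
    null = simulate_ils_null(
        tree_a, tree_b, ne_gene_copies, gen_time, n_sims, seed=seed
    )
    p = (1 + sum(1 for d in null if d >= d_obs)) / (1 + n_sims)
    return IlsTestResult(
        gene=gene,
        d_obs=d_obs,
        rf_obs=rf_obs,
        null=null,
        n_sims=n_sims,
        ne_gene_copies=ne_gene_copies,
        seed=seed,
        p_value=p,
    )


def _dissect_test_tree(tree: dendropy.Tree):
    """(light tree, placeholder clade, attachment node, anchor tip label)."""
    light = _snode_from_dendropy(tree)  # raises if not ultrametric

    def find_ph_clade(node, parent):
        labs = [l.label for l in node.leaves()]
        if all(l.startswith(PLACEHOLDER) for l in labs):
            return node, parent
        for c in node.children:
            hit = find_ph_clade(c, node)
            if hit is not None:
                return hit
        return None

    hit = find_ph_clade(light, None)
    if hit is None:
        raise ValueError("test tree has no placeholder (homoeologue) clade")
    ph_clade, attach = hit
    if attach is None:
        raise ValueError("homoeologue clade cannot span the whole test tree")
    anchor = next(
        l.label
        for c in attach.children
        if c is not ph_clade
        for l in c.leaves()
    )
    return light, ph_clade, attach, anchor


class _NullTemplate:
    """Precompiled backbone of one test tree's null model.

    The placeholder clade is stripped from the test tree; the remaining
    diploid backbone is compiled once into populations, and the chain of
    populations ancestral to the observed attachment is recorded so a
    replicate-specific release age only needs one edge split.
    """

    def __init__(self, tree: dendropy.Tree, ne_gene_copies: float):
        light, ph_clade, attach, anchor = _dissect_test_tree(tree)
        self.ph_tips = sorted(l.label for l in ph_clade.leaves())
        self.clade_root_age = ph_clade.age
        self.attach_age = attach.age
        self.ne = ne_gene_copies

        def strip(node):
            if not node.children:
                return SNode(label=node.label, age=0.0)
            kids = [strip(c) for c in node.children if c is not ph_clade]
            if len(kids) == 1:
                return kids[0]  # suppress the attachment unifurcation
            return SNode(age=node.age, children=kids)

        backbone = strip(light)
        pops: list[Population] = []
        tip_pid: dict[str, int] = {}
        pid_of: dict[int, int] = {}

        def walk(node: SNode, parent_age: float) -> int:
            pid = len(pops)
            pops.append(Population(pid=pid, t0=node.age, t1=parent_age,
                                   ne=ne_gene_copies))
            pid_of[id(node)] = pid
            for child in node.children:
                cpid = walk(child, node.age)
                pops[cpid].dest = pid
            if not node.children:
                tip_pid[node.label] = pid
            return pid

        walk(backbone, math.inf)
        self.base_pops = pops
        self.tip_pid = tip_pid

        # population chain ancestral to the anchor (the lineage that
        # carried the observed attachment)
        path: list[int] = []

        def descend(node) -> bool:
            if not node.children:
                hit = node.label == anchor
            else:
                hit = any(descend(c) for c in node.children)
            if hit:
                path.append(pid_of[id(node)])
            return hit

        descend(backbone)
        self.anchor_path = path  # tip -> root order

    def compile(self, t_release: float):
        """Populations for one replicate releasing pools at ``t_release``."""
        pops = [Population(p.pid, p.t0, p.t1, p.ne, p.dest)
                for p in self.base_pops]
        inject = None
        for pid in self.anchor_path:
            p = pops[pid]
            if p.t0 <= t_release < p.t1:
                if t_release == p.t0:
                    inject = pid
                else:
                    upper = Population(len(pops), t_release, p.t1, p.ne, p.dest)
                    pops.append(upper)
                    p.t1 = t_release
                    p.dest = upper.pid
                    inject = upper.pid
                break
        if inject is None:
            raise ValueError("release age not on the anchor lineage")
        pool_pids = []
        for _ in range(2):
            pid = len(pops)
            pops.append(Population(pid, 0.0, t_release, self.ne, dest=inject))
            pool_pids.append(pid)
        return pops, pool_pids


def simulate_ils_null(
    tree_a,
    tree_b,
    ne_gene_copies: float,
    gen_time: float,
    n_sims: int,
    seed: int | None = None,
) -> list[float]:
    """Null distances: ILS-only displacement of a single-origin clade.

    Each replicate simulates one gene tree in which two parallel pools of
    homoeologue lineages rise, mutually isolated (disomic), to a release
    age and then coalesce freely through the diploid backbone; the
    statistic is the branch-score distance between the gene tree
    restricted to pool 1 and restricted to pool 2 (diploid tips shared
    within the replicate, so backbone noise cancels exactly as it does
    between the two observed test trees).  The single-origin release age
    is only interval-censored by the data — it lies between the later of
    the two homoeologue-clade root ages and the earlier of the two
    attachment ages — so each replicate draws it uniformly from that
    interval.
    """
    rng = random.Random(seed)
    templates = [
        _NullTemplate(tree, ne_gene_copies) for tree in (tree_a, tree_b)
    ]
    t_hi = min(tpl.attach_age for tpl in templates)
    t_lo = min(max(tpl.clade_root_age for tpl in templates), t_hi)
    out = []
    for i in range(n_sims):
        tpl = templates[i % 2]
        t_release = rng.uniform(t_lo, t_hi) if t_hi > t_lo else t_hi
        pops, pool_pids = tpl.compile(t_release)
        entry: dict[int, list[LNode]] = {
            pid: [LNode(label=sp)] for sp, pid in tpl.tip_pid.items()
        }
        map1 = {sp: sp for sp in tpl.tip_pid}
        map2 = dict(map1)
        for tip in tpl.ph_tips:
            l1, l2 = tip + "&1", tip + "&2"
            entry.setdefault(pool_pids[0], []).append(LNode(label=l1))
            entry.setdefault(pool_pids[1], []).append(LNode(label=l2))
            map1[l1] = tip
            map2[l2] = tip
        g = simulate_populations(pops, entry, gen_time, rng)
        out.append(branch_score_light(g, g, map1, map2))
    return out


# ---------------------------------------------------------------------------
# Phased vs consensus comparison


def _clade_support(tree: dendropy.Tree, tips) -> float | None:
    """Support of the clade formed exactly by ``tips`` (None if not a clade)."""
    tips = set(tips)
    if len(tips) < 2:
        return None
    node = tree.mrca(taxon_labels=list(tips))
    if {l.taxon.label for l in node.leaf_iter()} != tips:
        return None
    return treekit.node_support(node)


def _attachment(tree: dendropy.Tree, tips) -> tuple[bool, set[str]]:
    """(monophyletic?, species of the sister group) for a set of tips."""
    tips = set(tips)
    if len(tips) == 1:
        node = next(
            l for l in tree.leaf_node_iter() if l.taxon.label in tips
        )
    else:
        node = tree.mrca(taxon_labels=list(tips))
    leafset = {l.taxon.label for l in node.leaf_iter()}
    if leafset != tips:
        return False, set()
    parent = node.parent_node
    if parent is None:
        return True, set()
    sisters = set()
    for sib in parent.child_nodes():
        if sib is node:
            continue
        sisters |= {species_of(l.taxon.label) for l in sib.leaf_iter()}
    return True, sisters


def compare_phased_vs_consensus(
    phased_alignments: dict[str, dict[str, str]],
    pileups: dict[str, dict[str, "object"]],
    tetraploid_labels=("T",),
    min_support: float = 0.9,
    n_boot: int = 0,
    seed: int | None = None,
) -> list[dict]:
    """Contrast origin signal in phased vs majority-consensus analyses.

    For each locus present in both representations, a gene tree is
    inferred from (a) the phased alleles and (b) one majority-consensus
    sequence per individual.  The record reports the pattern call under
    (a), the diploid species adjacent to each homoeologue clade (its
    "placement"), and whether either placement is recovered in (b): the
    tetraploid consensus tips must be monophyletic and their sister group
    must overlap the placement's species.  With ``n_boot`` > 0, both trees
    carry site-resampling bootstrap supports and each record reports the
    support behind every tetraploid placement, quantifying how much
    confidence the consensus representation erodes.
    """
    tetset = set(tetraploid_labels)
    records = []
    for locus, aln in phased_alignments.items():
        if locus not in pileups:
            records.append({"locus": locus, "skipped": "no pileups"})
            continue
        consensus_aln = {
            ind: majority_consensus(p) for ind, p in pileups[locus].items()
        }
        if len(consensus_aln) < 3:
            records.append({"locus": locus, "skipped": "too few individuals"})
            continue
        if n_boot > 0:
            phased_tree = treekit.bootstrap_support(aln, n_reps=n_boot,
                                                    seed=seed)
            cons_tree = treekit.bootstrap_support(consensus_aln,
                                                  n_reps=n_boot, seed=seed)
        else:
            phased_tree = treekit.infer_gene_tree(aln)
            cons_tree = treekit.infer_gene_tree(consensus_aln)
        clades = find_homoeologue_clades(
            phased_tree, tetset, min_support=min_support, gene=locus
        )
        pattern = classify_pattern(clades)
        mono_a, place_a = _attachment(phased_tree, clades.clade_a)
        mono_b, place_b = (
            _attachment(phased_tree, clades.clade_b)
            if clades.clade_b
            else (False, set())
        )
        place_a -= tetset
        place_b -= tetset
        cons_tips = [
            lab for lab in consensus_aln if species_of(lab) in tetset
        ]
        cons_mono, cons_sister = _attachment(cons_tree, cons_tips)
        cons_sister -= tetset
        supports = {}
        if n_boot > 0:
            supports = {
                "support_phased_a": _clade_support(phased_tree,
                                                   clades.clade_a),
                "support_phased_b": _clade_support(phased_tree,
                                                   clades.clade_b),
                "support_consensus_group": _clade_support(cons_tree,
                                                          cons_tips),
            }
        records.append(
            {
                "locus": locus,
                "pattern": pattern.pattern,
                **supports,
                "placement_a": sorted(place_a),
                "placement_b": sorted(place_b),
                "phased_placements_found": mono_a and mono_b,
                "consensus_monophyletic": cons_mono,
                "consensus_sister": sorted(cons_sister),
                "recovered_a": bool(cons_mono and place_a & cons_sister),
                "recovered_b": bool(cons_mono and place_b & cons_sister),
            }
        )
    return records


# ---------------------------------------------------------------------------
# AlloppNET-style input preparation


def export_pseudodiploids(
    allele_sets: list[PhasedAlleleSet],
    clades_by_locus: dict[str, HomoeologueClades],
) -> pd.DataFrame:
    """Assign one allele per homoeologue to two pseudo-individuals.

    Network models of allopolyploidy treat each subgenome as a separate
    "individual": every tetraploid sample is split into ``<sample>_1`` and
    ``<sample>_2``, each receiving one allele from each homoeologue clade
    per locus.  Loci whose alleles cannot all be assigned to a clade are
    flagged rather than silently assigned.
    """
    rows = []
    for pset in allele_sets:
        clades = clades_by_locus.get(pset.locus)
        if clades is None:
            continue
        in_a = {l for l in clades.clade_a if l.startswith(pset.individual + "|")}
        in_b = {l for l in clades.clade_b if l.startswith(pset.individual + "|")}
        for hom, members in (("A", in_a), ("B", in_b)):
            aids = sorted(lab.rsplit("|", 1)[1] for lab in members)
            for k, pseudo in enumerate((1, 2)):
                if not aids:
                    allele, flag = None, "missing_homoeologue"
                elif k < len(aids):
                    allele, flag = aids[k], ""
                else:
                    allele, flag = aids[-1], "allele_reused"
                rows.append(
                    {
                        "sample": pset.individual,
                        "locus": pset.locus,
                        "pseudo_individual": f"{pset.individual}_{pseudo}",
                        "homoeologue": hom,
                        "allele": allele,
                        "flag": flag,
                    }
                )
        assigned = {lab.rsplit("|", 1)[1] for lab in in_a | in_b}
        for aid in sorted(set(pset.alleles) - assigned):
            rows.append(
                {
                    "sample": pset.individual,
                    "locus": pset.locus,
                    "pseudo_individual": None,
                    "homoeologue": None,
                    "allele": aid,
                    "flag": "unassignable",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "locus",
            "pseudo_individual",
            "homoeologue",
            "allele",
            "flag",
        ],
    )
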