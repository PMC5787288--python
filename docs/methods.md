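# Methods

This note documents the models behind `polyorigin`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
experiments do and do not demonstrate.

## Scenario model

A scenario couples a dated diploid species tree with one tetraploid
lineage.  The diploid tree is a pectinate (ladder) template: the first
species splits at the crown age (default 11 Ma), the second at an internal
calibration age (default 6.14 Ma), and the remaining splits are spaced
evenly below the calibration.  A fixed template keeps experiments
interpretable and reproducible; the true topology used in any empirical
study is unknown anyway, and every operation accepts arbitrary ultrametric
trees.  Times are years before present; all tips are extant (age 0).

The tetraploid lineage is attached according to the mode of origin:

* **ALLO** — a single reticulation at the polyploidy time joins two donor
  lineages.  Inheritance is disomic from the start: each subgenome's two
  gene copies form an isolated pool that coalesces only internally until
  the hybridization event, then follows its own parental lineage.  Ground
  truth tags every haplotype with its subgenome (A/B).
* **AUTO** — genome doubling inside one progenitor lineage, no
  reticulation.  From the present back to the disomy-onset time the four
  copies sit in two (arbitrarily labelled) disomic pools; between disomy
  onset and the doubling they form one exchangeable tetrasomic pool; above
  the doubling they follow the progenitor.
* **SEGMENTAL** — each locus is tetrasomic with a configurable
  probability, disomic otherwise; the per-locus mode is recorded.

Coalescence happens within "populations" (branch intervals), each holding
`ne_gene_copies` copies: a pair coalesces at rate `1/(ne × generation
time)` per year, so one coalescent unit is `ne` generations (gene-copy
scaling; 1 Ma at 2-year generations and 204,000 copies ≈ 2.45 units).
Lineages that fail to coalesce within a branch move into the parent
branch.  The simulator matches the closed forms E[T₂] = `ne` generations
and P(no coalescence over t units) = e^(−t) within Monte-Carlo error, and
agrees with msprime under identical scaling (both checked in the tests).

Defaults reproduce the study design this package targets: ten unlinked
loci of 2572 bp, eight diploid species (one individual, two alleles each)
plus four tetraploid samples, substitution rate drawn per locus from a
normal distribution (mean 3.611 × 10⁻⁹, SD 1.357 × 10⁻⁹ substitutions per
site per year, truncated at zero), HKY+Γ sequences, 150 bp paired-end
reads at 60× per sample (within the reported 52.7–167× range), insert
500 ± 50 bp, base error rate 10⁻³.  The polyploidy time (2 Ma) and the
hybrid parents (the two deepest-diverging diploids) are not stated by any
source and were fixed once as a deep, clearly allopolyploid reference
condition.

## Sequences and reads

Sequences evolve under HKY with empirical-style base frequencies
(0.3/0.2/0.2/0.3) and κ = 3, with gamma rate heterogeneity discretized to
four equal-probability categories (category rate = mean of its quartile);
shape 0.8 by default, `None` disables heterogeneity.  Transition
probabilities come from an eigendecomposition of the rate matrix
normalized to one expected substitution per site per unit branch length;
rows are clipped to [0, 1] and renormalized to absorb floating-point
noise.  No indels are simulated: sequences are born aligned, and reads are
born placed on the locus coordinate system.

Read pairs are placed uniformly on a window extending one insert length
beyond each locus end and clipped to the locus — capture targets sit
inside larger sequenced fragments, so coverage is uniform across the
aligned region rather than ramping to zero at the edges.  The pair count
is scaled so realized coverage matches `depth_mean`; per-haplotype counts
are multinomial.  PCR duplicates (exact copies of existing pairs) can be
re-emitted at a configurable rate to exercise the deduplication rule.

## Phasing

Heterozygous sites require at least `min_support = 3` *independent* reads
per base state: reads identical in start, mate start and sequence are
collapsed first, so PCR duplicates cannot manufacture support.  Fragments
(mate pairs) are then segregated into two groups.  Groups are seeded from
the most *balanced* well-supported het site — a ~50/50 split separates the
two groups, whereas a skewed site may be polymorphism within one group —
and grown by a smoothed per-site log-likelihood: a fragment joins the
group under whose observed base profile its alleles are most probable
(add-half smoothing).  Using the full profile rather than the consensus
matters when a group is itself polymorphic at a site: a rare but genuine
state must not be pushed toward the group that merely lacks it.  After
convergence two repair passes run: (i) every fragment is re-scored against
the final profiles (fixing early misassignments), and (ii) coherent
*switch errors* — both groups phase-inverted beyond some column, a local
optimum single-fragment moves cannot leave — are detected from fragments
that agree with their own group on one side of a boundary and with the
other group beyond it, and repaired by flipping the block.  Fragments
covering no informative site are assigned pseudo-randomly and flagged;
het-site islands disconnected from the main block are phased internally
and attached as whole blocks (the inter-block phase is a documented
switching hazard), never scattered read by read.

Each group is then re-examined with the same support rule; residual
polymorphism splits it into two allelic variants, yielding one to four
alleles.  A column with more than two supported states within one group is
flagged (`over_ploid`) and no fifth allele is emitted.  Draft and allele
sequences are per-column majorities over their own reads; columns without
coverage are `N`, so no allele base ever lacks a supporting read.

**Exact-recovery preconditions.**  Exact reconstruction of all four
haplotypes from error-free reads is only well-posed when the reads
identify it: every true polymorphic state needs `min_support` independent
templates, adjacent subgenome-diagnostic sites and adjacent
within-subgenome sites must be bridged by fragments, and no
polymorphism-touching fragment may be blind to all diagnostic sites.
`exact_recovery_conditions_met` checks these properties of the read set
(they are conditions on the data, not on the algorithm); at the default
depth roughly one locus in six qualifies, and on qualifying loci phasing
recovers the exact set of distinct true haplotypes (the exactness
experiment demands 100/100).  Two identical haplotypes (a
homozygous subgenome) are reported as one allele — a read-based method
cannot count indistinguishable copies, and allele number below
2 × ploidy is itself informative about homozygosity.

## Recombination screen

Phasing and contig joining can splice the 5′ part of one allele onto the
3′ part of another.  Each sequence triplet is scanned with a MaxChi-style
statistic: for every pair in the triplet, the maximum 2×2 chi-square
contrasting mismatch counts left vs right of a breakpoint sliding over the
triplet's variable sites.  Significance comes from permuting site order
(1000 permutations at the p < 0.1 screening tier; 10,000 with Bonferroni
correction over triplets at the p < 0.01 confirmation tier — the
correction is this package's choice).  Two confirmed events sharing a
breakpoint that coincides with a recorded contig boundary (±5 bp) are
repaired by swapping the allele ends back (an involution); any other
event has the shorter side of its breakpoint masked to `N`.  Alignment
length and allele count never change.

## Diversity and effective size

Watterson's θ_w = S / (a_{n−1} L) per site, with columns containing any
missing data excluded from both S and L by default (`max_missing`
configurable).  On gene-copy scaling θ_w = 2 N μ_gen, so
N = θ_w / (2 μ_year g) gene copies, and individuals are gene copies / 2.
Zero-θ estimates (no polymorphism in a small allele sample) are treated as
sampling noise: before averaging, they are recomputed using the smallest
positive θ_w observed across estimates.  Quantiles use linear
interpolation; the reporting mode rounds to three significant figures.
On 500 simulated single-population loci (n = 6, θ = 0.01, homogeneous
rates to isolate the estimator from rate-heterogeneity bias) the mean
estimate is within a few percent of truth — the residual deficit is
finite-sites saturation, not an estimator defect.

## Gene trees and comparison

Internal tree inference is neighbor joining on HKY-corrected distances
(the Tamura–Nei closed form, which contains HKY; saturated pairs fall back
to p-distance and are flagged), with deterministic lexicographic
tie-breaking, negative branch lengths clamped to zero, and midpoint
rooting unless an outgroup is named.  Site-resampling bootstrap
proportions can be attached as supports.  This is a deliberately
deterministic desk-scale substitute for Bayesian inference; dated trees
from external software are accepted as first-class inputs wherever a tree
is consumed.

Tree comparison offers the unrooted Robinson–Foulds bipartition count and
the continuous branch-score (Kuhner–Felsenstein) distance, both computed
on the shared-taxon restriction.

## Pattern classification

The classifier finds the maximal clades consisting purely of tetraploid
alleles.  Exactly two, non-sister, with at least one supported node
(support ≥ 0.9 by default; absent supports are taken at face value)
between them → **ALLO_LIKE**; a single clade (reported as its two daughter
subclades with `sister=True`) → **AUTO_LIKE**; tetraploid alleles stranded
outside the two main clades → **INCOMPLETE_FIXATION** (the signature of
incomplete allele fixation under tetrasomy); anything else →
**UNRESOLVED**.  On true gene trees from deep scenarios (parental
divergence ≈ 22 coalescent units; auto fixation ≈ 10 units) the classifier
is ≥ 95% accurate in both directions; errors are genuine deep-coalescence
events, not classifier artifacts.

## The hybridization-vs-ILS test

From a gene tree with two homoeologue clades, two *test trees* are built
by alternately pruning one clade while keeping all diploid alleles; the
retained clade's tips are renamed to a shared placeholder series, so the
trees are identical except for where the homoeologue attaches.  The
observed statistic d_obs is the branch-score distance between them (the
RF count is reported alongside; the branch-score was chosen because an
add-one Monte-Carlo test on the integer-valued RF cannot reach nominal
levels — its atoms cap the achievable type-I error well below α).

The null hypothesis is that both placements descend from a *single*
origin, displaced only by incomplete lineage sorting.  Each null replicate
re-enacts that process inside a test tree treated as the species history
(constant Ne on all branches, per the study design): two pools of
homoeologue lineages rise from the present, mutually isolated below the
release age exactly as disomic subgenomes are, are released into the
backbone at the observed attachment, and coalesce freely; the replicate's
statistic is the branch-score distance between the two single-pool
restrictions of the one simulated gene tree.  Sharing a single backbone
realization per replicate mirrors the observed statistic, whose two test
trees share their diploid backbone by construction — simulating two
independent gene trees instead would add backbone noise the observed
statistic cannot contain (and, worse, simulating one tree inside *each*
test tree embeds the observed displacement itself in the null, making
rejection impossible).  The release age is only interval-censored by the
data — it lies between the later of the two homoeologue-clade root ages
and the earlier of the two attachment ages — so each replicate draws it
uniformly from that interval.  Replicates alternate between the two test
trees; p = (1 + #{d_null ≥ d_obs}) / (1 + n_sims), which is always
positive.

Calibration was measured on ILS-only data in the regime where the test is
actually needed (tetrasomic pools released into a ladder of short
backbone internodes, so non-sister patterns arise without hybridization):
the rejection rate at α = 0.05 over 200 tested loci falls near 2.5–3.5%
— slightly conservative, never anti-conservative.  Power on deep hybrids
(parents ≥ 8 coalescent units apart) is essentially 1 at p < 0.01.  Loci
whose gene trees do not present two clean homoeologue clades are not
testable and are reported as such.

## Phased vs consensus comparison

For each locus, gene trees are inferred from (a) the phased alleles and
(b) one majority-consensus sequence per individual (modal base per column,
ties broken A<C<G<T).  A tetraploid consensus is a chimera of four
haplotypes; at subgenome-diagnostic columns the 2:2 tie makes it a
random mosaic of the two parents.  The comparison reports, per locus, the
pattern call under (a), each homoeologue's placement (the diploid species
in its sister group), and whether the consensus tree recovers either
placement (tetraploid consensus tips monophyletic with a sister group
overlapping the placement).  In the deep-ALLO experiment, on loci where
the phased tree recovers both true parents, the consensus tree recovers
neither in ≥ 80% (typically all) of loci — consensus sequences do not
merely blur the hybrid signal, they erase it.

## Pseudo-diploid export

For network analyses that model each subgenome as a separate "individual",
every tetraploid sample is split into `<sample>_1` and `<sample>_2`, each
assigned one allele per homoeologue clade per locus (sorted allele order;
a single allele in a clade is reused with a flag; alleles in neither clade
are flagged `unassignable`, never silently assigned).

## Problem sizes and runtime

The reference experiments are sized to finish in a few minutes on one
CPU: 10,000 coalescent replicates for the deep-coalescence check, 20
identifiable loci for exact phasing recovery, 500 loci for θ recovery,
200 tested loci × 500 null simulations for calibration, 100 × 500 for
power, 200 + 200 loci for classification, 25 loci for the consensus
comparison, and 30 chimeras plus 200 clonal alignments for MaxChi.  The
pipeline demonstration uses the default ten-locus scenario.

## Known limitations

* No indel evolution, structural variation, mapping or assembly
  simulation; reads are born aligned, so real-data phasing additionally
  depends on mapping quality the simulator does not model.
* The diploid species tree is a fixed ladder template; topology-dependent
  quantities (e.g. which diploids sit next to a homoeologue) should be
  read as illustrative, not exhaustive over tree shapes.
* One individual per diploid species; population structure within
  diploids is not modelled.
* The ILS test conditions on the observed attachment points and is mildly
  conservative; its null also assumes one constant population size on all
  branches.
* Passing synthetic experiments shows the algorithms are correct under
  the generative model; real data add error sources (indels, paralogy,
  mapping artifacts, base-quality structure) the model excludes.
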