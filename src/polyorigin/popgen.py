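"""Allelic diversity and effective population size.

Watterson's estimator relates the number of segregating sites S observed
among n sampled allele sequences to the population-scaled mutation rate:
theta_w = S / (a_{n-1} * L) per site, with a_{n-1} the harmonic number
sum_{i=1}^{n-1} 1/i and L the number of scored columns.  On the
gene-copy (haploid) coalescent scaling used throughout this package,
theta_w = 2 * N_gc * mu_gen, so an effective size in gene copies follows
as N_gc = theta_w / (2 * mu_year * g) given a per-year mutation rate and
a generation time g.  Diploid individual counts are gene copies / 2.

Per-clade estimates of zero (no polymorphism observed in a small sample)
are treated as sampling noise, not as a zero population: when summarizing
across estimates, zero-theta entries are recomputed using the smallest
positive theta observed overall before averaging.

One coalescent unit is N_gc generations; two lineages entering a branch
of t units fail to coalesce within it with probability exp(-t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThetaEstimate",
    "NeEstimate",
    "NeSummary",
    "watterson_theta",
    "effective_size",
    "summarize_ne",
    "coalescent_units",
    "prob_retained_polymorphism",
    "harmonic_number",
]


def harmonic_number(m: int) -> float:
    return sum(1.0 / i for i in range(1, m + 1))


@dataclass
class ThetaEstimate:
    clade: str
    n: int  # alleles sampled
    S: int  # segregating sites
    L: int  # scored columns
    a: float  # harmonic number a_{n-1}
    theta_w: float  # per site


@dataclass
class NeEstimate:
    clade: str
    theta_w: float
    mu_year: float
    gen_time: float
    ne_gene_copies: float


@dataclass
class NeSummary:
    n_estimates: int
    substituted: list[int]  # indices recomputed with the minimum positive theta
    mean: float
    median: float
    q1: float
    q3: float

    @property
    def mean_individuals(self) -> float:
        return self.mean / 2.0

    @property
    def median_individuals(self) -> float:
        return self.median / 2.0

    def report(self, sig: int = 3) -> dict:
        def r(x):
            if x == 0:
                return 0.0
            return float(f"{x:.{sig}g}")

        return {
            "mean_gene_copies": r(self.mean),
            "median_gene_copies": r(self.median),
            "q1_gene_copies": r(self.q1),
            "q3_gene_copies": r(self.q3),
            "mean_individuals": r(self.mean_individuals),
            "median_individuals": r(self.median_individuals),
        }


def watterson_theta(
    alignment, max_missing: float = 0.0, clade: str = "clade"
) -> ThetaEstimate:
    """Watterson's theta per site from aligned allele sequences.

    Columns whose fraction of missing characters (anything outside ACGT)
    exceeds ``max_missing`` are excluded from both S and L; segregating
    sites are columns with >= 2 distinct non-missing states.
    """
    if isinstance(alignment, dict):
        seqs = [alignment[k] for k in sorted(alignment)]
    else:
        seqs = [s for _, s in alignment] if alignment and isinstance(
            alignment[0], tuple
        ) else list(alignment)
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    mat = np.vstack([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    included = (1.0 - valid.mean(axis=0)) <= max_missing
    L = int(included.sum())
    if L == 0:
        raise ValueError("no scorable columns")
    cols = np.nonzero(included)[0]
    S = 0
    for c in cols:
        states = set(mat[valid[:, c], c].tolist())
        if len(states) >= 2:
            S += 1
    a = harmonic_number(n - 1)
    return ThetaEstimate(clade=clade, n=n, S=S, L=L, a=a, theta_w=S / (a * L))


def effective_size(theta: float, mu_year: float, gen_time: float,
                   clade: str = "clade") -> NeEstimate:
    """Effective size in gene copies: theta / (2 * mu_year * gen_time)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if mu_year <= 0 or gen_time <= 0:
        raise ValueError("mutation rate and generation time must be > 0")
    return NeEstimate(
        clade=clade,
        theta_w=theta,
        mu_year=mu_year,
        gen_time=gen_time,
        ne_gene_copies=theta / (2.0 * mu_year * gen_time),
    )


def summarize_ne(estimates: list[NeEstimate]) -> NeSummary:
    """Mean/median/quartiles over Ne estimates with the zero-theta rule.

    Entries with theta_w == 0 are recomputed using the smallest positive
    theta_w among all estimates (an effective population size cannot
    realistically be zero; a zero estimate reflects the chance absence of
    polymorphism in a small sample).  Quantiles use linear interpolation.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    thetas = [e.theta_w for e in estimates]
    positive = [t for t in thetas if t > 0]
    if not positive:
        raise ValueError("all theta estimates are zero; no substitute exists")
    floor = min(positive)
    substituted = [i for i, t in enumerate(thetas) if t == 0]
    values = []
    for i, e in enumerate(estimates):
        if i in substituted:
            values.append(floor / (2.0 * e.mu_year * e.gen_time))
        else:
            values.append(e.ne_gene_copies)
    arr = np.asarray(sorted(values), dtype=float)
    return NeSummary(
        n_estimates=len(values),
        substituted=substituted,
        mean=float(arr.mean()),
        median=float(np.quantile(arr, 0.5)),
        q1=float(np.quantile(arr, 0.25)),
        q3=float(np.quantile(arr, 0.75)),
    )


def coalescent_units(duration: float, gen_time: float, ne_gene_copies: float) -> float:
    """Duration in coalescent units: years / (generation time * N gene copies)."""
    if gen_time <= 0 or ne_gene_copies <= 0:
        raise ValueError("gen_time and ne_gene_copies must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    return duration / gen_time / ne_gene_copies


def prob_retained_polymorphism(t_cu: float) -> float:
    """P(two lineages fail to coalesce across a branch of t coalescent units)."""
    if t_cu < 0:
        raise ValueError("coalescent time must be >= 0")
    return math.exp(-t_cu)
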