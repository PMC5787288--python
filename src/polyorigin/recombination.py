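"""MaxChi-style recombination screening of phased alleles.

Phasing short reads can manufacture chimeric alleles: a switching error
(or the manual joining of partially overlapping contigs) splices the 5'
part of one allele onto the 3' part of another.  Between homoeologues of
an allopolyploid such a chimera mixes sequence of two parental origins,
which is fatal for origin inference, so every phased alignment is
screened before use.

The statistic follows the MaxChi idea: for a pair of sequences within a
triplet, a recombination breakpoint shows up as a step change in the
match/mismatch rate along the alignment, and the best 2x2 chi-square
contrasting mismatch counts left vs right of a sliding breakpoint is the
evidence.  Significance comes from permuting site order (which destroys
positional clustering but preserves the mismatch total), at a permissive
screening level first and a stricter confirmation level (with more
permutations and a Bonferroni correction over triplets) second.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .treekit import encode_sequences
from .phasing import PhasedAlleleSet

__all__ = [
    "RecombinationEvent",
    "maxchi_scan",
    "confirm_events",
    "resolve_chimeras",
]


@dataclass
class RecombinationEvent:
    """A putative recombination breakpoint in one sequence."""

    sequence: str
    partner: str
    outgroup: str | None
    breakpoint: tuple[int, int]  # 0-based half-open alignment interval
    p_screen: float
    chi: float
    p_confirm: float | None = None
    boundary_matched: bool = False
    action: str | None = None


def _max_chi_curve(cum: np.ndarray, V: int, T: np.ndarray) -> np.ndarray:
    """Chi-square at every breakpoint from cumulative mismatch counts.

    ``cum``: (..., V) cumulative sums of a mismatch indicator; returns
    (..., V-1) chi-square values for left blocks of size 1..V-1.
    """
    k = np.arange(1, V, dtype=float)
    a = cum[..., :-1]  # mismatches left of the breakpoint
    T = np.asarray(T, dtype=float)[..., None]
    b = k - a
    c = T - a
    d = (V - k) - c
    den = k * (V - k) * T * (V - T)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = V * (a * d - b * c) ** 2 / den
    return np.where(den > 0, chi, 0.0)


def _triplet_columns(mat: np.ndarray, tri) -> np.ndarray:
    sub = mat[list(tri)]
    ok = (sub >= 0).all(axis=0)
    varying = (sub != sub[0]).any(axis=0)
    return np.nonzero(ok & varying)[0]


def maxchi_scan(
    alignment,
    p_screen: float = 0.1,
    seed: int | None = None,
    n_perm: int = 1000,
) -> list[RecombinationEvent]:
    """Screen every sequence triplet for a recombination breakpoint.

    For each triplet, the mismatch vectors of its three pairs are scanned
    over the triplet's variable sites; the statistic is the maximum 2x2
    chi-square over breakpoints and pairs, calibrated by ``n_perm``
    permutations of site order.  Candidates with p < ``p_screen`` are
    returned with the best breakpoint mapped back to alignment
    coordinates (the interval between the flanking variable sites).
    """
    labels, mat = encode_sequences(alignment)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 sequences to scan for recombination")
    rng = np.random.default_rng(seed)
    events: list[RecombinationEvent] = []
    for tri in itertools.combinations(range(n), 3):
        cols = _triplet_columns(mat, tri)
        V = len(cols)
        if V < 4:
            continue
        pair_idx = [(0, 1), (0, 2), (1, 2)]
        sub = mat[list(tri)][:, cols]
        M = np.stack([sub[i] != sub[j] for i, j in pair_idx]).astype(np.int64)
        T = M.sum(axis=1)
        obs_curves = _max_chi_curve(np.cumsum(M, axis=1), V, T)
        obs = float(obs_curves.max())
        flat = int(np.argmax(obs_curves))
        best_pair, best_k = divmod(flat, V - 1)
        best_k += 1  # left block size
        # permute site order (shared across the triplet's three pairs)
        perm = np.tile(np.arange(V), (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        pm = M[:, perm]  # (3, n_perm, V)
        curves = _max_chi_curve(np.cumsum(pm, axis=2), V, T[:, None] * np.ones(n_perm))
        null_max = curves.max(axis=(0, 2))
        p = (1 + int((null_max >= obs).sum())) / (1 + n_perm)
        if p < p_screen:
            i, j = pair_idx[best_pair]
            lo = int(cols[best_k - 1]) + 1
            hi = int(cols[best_k]) + 1
            events.append(
                RecombinationEvent(
                    sequence=labels[tri[i]],
                    partner=labels[tri[j]],
                    outgroup=labels[tri[3 - i - j]],
                    breakpoint=(lo, hi),
                    p_screen=p,
                    chi=obs,
                )
            )
    return events


def confirm_events(
    alignment,
    candidates,
    p_confirm: float = 0.01,
    n_perm: int = 10000,
    seed: int | None = None,
    bonferroni: bool = True,
) -> list[RecombinationEvent]:
    """Re-check screening candidates at the stricter level.

    Each candidate's triplet is re-evaluated with ``n_perm`` permutations;
    the p-value is Bonferroni-adjusted for the number of triplets scanned
    and the event retained when the adjusted p falls below ``p_confirm``.
    """
    if not candidates:
        return []
    labels, mat = encode_sequences(alignment)
    index = {lab: i for i, lab in enumerate(labels)}
    n_triplets = max(
        1, len(labels) * (len(labels) - 1) * (len(labels) - 2) // 6
    )
    rng = np.random.default_rng(seed)
    confirmed = []
    for ev in candidates:
        tri = tuple(
            sorted(index[x] for x in (ev.sequence, ev.partner, ev.outgroup))
        )
        cols = _triplet_columns(mat, tri)
        V = len(cols)
        if V < 4:
            continue
        sub = mat[list(tri)][:, cols]
        pair_idx = [(0, 1), (0, 2), (1, 2)]
        M = np.stack([sub[i] != sub[j] for i, j in pair_idx]).astype(np.int64)
        T = M.sum(axis=1)
        obs = float(_max_chi_curve(np.cumsum(M, axis=1), V, T).max())
        exceed = 0
        block = 2000  # bound permutation memory
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            perm = rng.permuted(np.tile(np.arange(V), (b, 1)), axis=1)
            pm = M[:, perm]
            curves = _max_chi_curve(
                np.cumsum(pm, axis=2), V, T[:, None] * np.ones(b)
            )
            exceed += int((curves.max(axis=(0, 2)) >= obs).sum())
            done += b
        p = (1 + exceed) / (1 + n_perm)
        p_adj = min(1.0, p * n_triplets) if bonferroni else p
        if p_adj < p_confirm:
            confirmed.append(_dc_replace(ev, p_confirm=p_adj))
    return confirmed


def resolve_chimeras(
    alleles: PhasedAlleleSet,
    events,
    contig_boundaries,
    tol: int = 5,
) -> PhasedAlleleSet:
    """Repair or mask confirmed chimeric alleles.

    Two events whose breakpoints agree (within ``tol``) and coincide with
    a recorded contig boundary are interpreted as an in-silico switching
    error introduced when fragments were joined: the two alleles' ends
    beyond the boundary are swapped back.  Any other event has its minimal
    recombinant segment (the shorter side of the breakpoint) replaced by
    Ns.  Alignment length and allele count are never changed.
    """
    new_alleles = dict(alleles.alleles)
    decisions = list(alleles.decisions)
    flags = set(alleles.flags)
    for ev in events:
        if ev.sequence not in new_alleles:
            raise ValueError(f"event references unknown allele {ev.sequence!r}")

    def nearest_boundary(ev):
        lo, hi = ev.breakpoint
        for b in contig_boundaries:
            if lo - tol <= b <= hi - 1 + tol:
                return b
        return None

    used = set()
    events = list(events)
    for i, ev in enumerate(events):
        if i in used:
            continue
        b = nearest_boundary(ev)
        partner_idx = None
        if b is not None:
            for j in range(i + 1, len(events)):
                if j in used or events[j].sequence == ev.sequence:
                    continue
                if nearest_boundary(events[j]) == b:
                    partner_idx = j
                    break
        if b is not None and partner_idx is not None:
            other = events[partner_idx]
            s1, s2 = ev.sequence, other.sequence
            a1, a2 = new_alleles[s1], new_alleles[s2]
            new_alleles[s1] = a1[:b] + a2[b:]
            new_alleles[s2] = a2[:b] + a1[b:]
            ev.boundary_matched = other.boundary_matched = True
            ev.action = other.action = "swap"
            used.update((i, partner_idx))
            decisions.append(f"swap {s1} <-> {s2} at contig boundary {b}")
        else:
            lo, hi = ev.breakpoint
            mid = (lo + hi) // 2
            seq = new_alleles[ev.sequence]
            L = len(seq)
            if mid <= L - mid:
                masked = "N" * mid + seq[mid:]
                span = (0, mid)
            else:
                masked = seq[:mid] + "N" * (L - mid)
                span = (mid, L)
            new_alleles[ev.sequence] = masked
            ev.action = "mask"
            used.add(i)
            flags.add("recombinant_masked")
            decisions.append(
                f"mask {ev.sequence} [{span[0]}, {span[1]}) (no boundary match)"
            )
    return PhasedAlleleSet(
        individual=alleles.individual,
        locus=alleles.locus,
        alleles=new_alleles,
        support=dict(alleles.support),
        flags=flags,
        decisions=decisions,
    )
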