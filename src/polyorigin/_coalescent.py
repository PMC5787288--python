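"""Structured-coalescent core shared by the simulator and the ILS test.

Everything here works on deliberately lightweight tree nodes (``LNode``)
rather than dendropy objects: the hybridization-vs-ILS test simulates
hundreds of thousands of small gene trees and the conversion/bookkeeping
overhead of a full tree library would dominate runtime otherwise.  The
stdlib ``random.Random`` is used for the same reason (numpy Generator call
overhead is large relative to one exponential draw).

Time is measured in years before present (tips at age 0, ages increasing
toward the root).  A population is an interval ``[t0, t1)`` on that axis
with a constant number of gene copies ``ne``; within it each pair of
lineages coalesces at rate ``1 / (ne * gen_time)`` per year (one pair per
``ne`` generations).  Populations form a tree via ``dest``: lineages
surviving to ``t1`` are handed to the destination population whose ``t0``
equals this ``t1``.  The root population has ``dest is None`` and
``t1 = inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LNode",
    "Population",
    "simulate_populations",
    "SNode",
    "populations_from_species_tree",
    "bipartitions",
    "rf_distance_light",
    "newick_of",
    "leaf_labels",
]


class LNode:
    """Minimal rooted tree node: ``label`` is None for internal nodes."""

    __slots__ = ("label", "age", "children", "meta")

    def __init__(self, label=None, age=0.0, children=None, meta=None):
        self.label = label
        self.age = age
        self.children = children if children is not None else []
        self.meta = meta

    def leaves(self):
        stack, out = [self], []
        while stack:
            n = stack.pop()
            if n.children:
                stack.extend(n.children)
            else:
                out.append(n)
        return out

    def preorder(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)


@dataclass
class Population:
    """One constant-size interval of a structured-coalescent history."""

    pid: int
    t0: float
    t1: float  # math.inf for the root population
    ne: float  # gene copies
    dest: int | None = None


def _coalesce_interval(lineages, t0, t1, ne, gen_time, rng):
    """Coalesce ``lineages`` (list of LNode) in place over [t0, t1)."""
    t = t0
    k = len(lineages)
    scale = ne * gen_time
    while k >= 2:
        rate = k * (k - 1) / 2.0 / scale
        t += rng.expovariate(rate)
        if t >= t1:
            break
        i = rng.randrange(k)
        j = rng.randrange(k - 1)
        if j >= i:
            j += 1
        parent = LNode(age=t, children=[lineages[i], lineages[j]])
        lineages[i] = parent
        lineages[j] = lineages[k - 1]
        lineages.pop()
        k -= 1
    return lineages


def simulate_populations(populations, entry, gen_time, rng):
    """Run the structured coalescent over a population tree.

    Parameters
    ----------
    populations : list of Population
    entry : dict pid -> list of LNode
        Sampled lineages entering each population at its ``t0``.
    gen_time : float
        Years per generation.
    rng : random.Random

    Returns
    -------
    LNode
        The grand MRCA of all sampled lineages.
    """
    if not entry or not any(entry.values()):
        raise ValueError("empty sample: no lineages to simulate")
    pending = {pid: list(lins) for pid, lins in entry.items()}
    # Populations only feed forward in time, so processing in order of end
    # time guarantees a population's inputs are complete when it is reached.
    for pop in sorted(populations, key=lambda p: (p.t1, p.t0)):
        lins = pending.pop(pop.pid, None)
        if not lins:
            continue
        survivors = _coalesce_interval(lins, pop.t0, pop.t1, pop.ne, gen_time, rng)
        if pop.dest is None:
            if len(survivors) != 1:
                raise RuntimeError("root population did not fully coalesce")
            return survivors[0]
        pending.setdefault(pop.dest, []).extend(survivors)
    raise ValueError("lineages never reached a root population")


# ---------------------------------------------------------------------------
# Species trees as population structures


class SNode:
    """Light species-tree node used to compile population structures."""

    __slots__ = ("label", "age", "children")

    def __init__(self, label=None, age=0.0, children=None):
        self.label = label
        self.age = age
        self.children = children if children is not None else []

    def leaves(self):
        stack, out = [self], []
        while stack:
            n = stack.pop()
            if n.children:
                stack.extend(n.children)
            else:
                out.append(n)
        return out


def populations_with_injection(
    root: SNode, ne: float, anchor_tip: str, t_inject: float
):
    """Compile a species tree, splitting one edge at an injection time.

    The edge ancestral to ``anchor_tip`` that spans ``t_inject`` is split
    there, so external lineages can enter the tree at that point.
    Returns (populations, tip_pid, inject_pid).
    """
    populations: list[Population] = []
    tip_pid: dict[str, int] = {}
    inject = {"pid": None}

    def on_path(node: SNode) -> bool:
        if not node.children:
            return node.label == anchor_tip
        return any(on_path(c) for c in node.children)

    def walk(node: SNode, parent_age: float) -> int:
        lower = len(populations)
        populations.append(Population(pid=lower, t0=node.age, t1=parent_age, ne=ne))
        top = lower
        if on_path(node) and node.age <= t_inject < parent_age:
            if t_inject > node.age:
                populations[lower].t1 = t_inject
                top = len(populations)
                populations.append(
                    Population(pid=top, t0=t_inject, t1=parent_age, ne=ne)
                )
                populations[lower].dest = top
            inject["pid"] = top
        for child in node.children:
            ctop = walk(child, node.age)
            populations[ctop].dest = lower
        if not node.children:
            tip_pid[node.label] = lower
        return top

    walk(root, math.inf)
    if inject["pid"] is None:
        raise ValueError("injection point not found on anchor path")
    return populations, tip_pid, inject["pid"]


def bipartition_lengths(root: LNode, label_map: dict) -> dict:
    """Edge lengths keyed by (canonical) bipartition after leaf renaming.

    Leaves absent from ``label_map`` are dropped; edges merged by the
    restriction have their lengths summed.  Terminal edges are included,
    so the result supports branch-score comparisons.
    """
    shared = set(label_map.values())
    if len(shared) < 2:
        raise ValueError("need at least 2 mapped taxa")
    ref = min(shared)
    n = len(shared)
    acc: dict[frozenset, float] = {}

    def walk(node: LNode, parent_age: float):
        if not node.children:
            s = {label_map[node.label]} if node.label in label_map else set()
        else:
            s = set()
            for c in node.children:
                s |= walk(c, node.age)
        if not math.isinf(parent_age) and 0 < len(s) < n:
            side = frozenset(s if ref not in s else shared - s)
            acc[side] = acc.get(side, 0.0) + (parent_age - node.age)
        return s

    walk(root, math.inf)
    return acc


def branch_score_light(t1: LNode, t2: LNode, map1: dict, map2: dict) -> float:
    """Kuhner-Felsenstein branch-score distance after leaf renaming."""
    d1 = bipartition_lengths(t1, map1)
    d2 = bipartition_lengths(t2, map2)
    total = 0.0
    for key in d1.keys() | d2.keys():
        diff = d1.get(key, 0.0) - d2.get(key, 0.0)
        total += diff * diff
    return math.sqrt(total)


def bipartitions_mapped(root: LNode, label_map: dict):
    """Bipartitions after renaming leaves via ``label_map`` (others dropped)."""

    def rename(n: LNode) -> LNode:
        if not n.children:
            return LNode(label=label_map.get(n.label), age=n.age)
        return LNode(age=n.age, children=[rename(c) for c in n.children])

    pruned = rename(root)
    return bipartitions(pruned, set(label_map.values()))


def populations_from_species_tree(root: SNode, ne: float):
    """Compile an ultrametric species tree into Populations.

    Each node owns the population on the edge above it, spanning
    [node.age, parent.age); the root population is open-ended.  Returns
    ``(populations, tip_pid)`` where ``tip_pid`` maps tip label -> pid of
    its terminal population.
    """
    populations: list[Population] = []
    tip_pid: dict[str, int] = {}

    def walk(node: SNode, parent_age: float) -> int:
        pid = len(populations)
        populations.append(Population(pid=pid, t0=node.age, t1=parent_age, ne=ne))
        if node.children:
            for child in node.children:
                cpid = walk(child, node.age)
                populations[cpid].dest = pid
        else:
            tip_pid[node.label] = pid
        return pid

    walk(root, math.inf)
    return populations, tip_pid


# ---------------------------------------------------------------------------
# Bipartitions / Robinson-Foulds on light trees


def leaf_labels(root: LNode):
    return [n.label for n in root.leaves()]


def bipartitions(root: LNode, taxa=None):
    """Non-trivial unrooted bipartitions restricted to ``taxa``.

    Returns a set of frozensets; each frozenset is the canonical side (the
    side *not* containing the lexicographically smallest shared taxon).
    Restriction to a taxon subset is part of the operation so that trees on
    different full taxon sets can be compared on their overlap.
    """
    all_leaves = set(leaf_labels(root))
    shared = all_leaves if taxa is None else (all_leaves & set(taxa))
    if len(shared) < 4:
        raise ValueError("need at least 4 shared taxa for bipartitions")
    ref = min(shared)
    n = len(shared)
    out = set()

    def clade(node):
        if not node.children:
            return {node.label} if node.label in shared else set()
        s = set()
        for c in node.children:
            s |= clade(c)
        if 1 < len(s) < n - 1:
            side = s if ref not in s else shared - s
            out.add(frozenset(side))
        return s

    clade(root)
    return out


def rf_distance_light(t1: LNode, t2: LNode):
    """Unrooted RF distance on the shared-taxon restriction of two trees."""
    shared = set(leaf_labels(t1)) & set(leaf_labels(t2))
    return len(bipartitions(t1, shared) ^ bipartitions(t2, shared))


def newick_of(root: LNode, digits: int = 12) -> str:
    """Serialize an LNode tree to Newick with branch lengths in years."""

    def fmt(x):
        return ("%." + str(digits) + "g") % x

    def rec(node, parent_age):
        if node.children:
            core = "(" + ",".join(rec(c, node.age) for c in node.children) + ")"
        else:
            core = node.label
        if parent_age is None or math.isinf(parent_age):
            return core
        return core + ":" + fmt(max(parent_age - node.age, 0.0))

    return rec(root, None) + ";"
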