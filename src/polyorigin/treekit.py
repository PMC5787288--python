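"""Tree I/O, distance-based gene-tree inference, comparison and pruning.

Trees are represented as rooted :class:`dendropy.Tree` objects with tip
labels following the ``<species>|<individual>|<allele>`` convention used
throughout the package.  Branch lengths are either years (simulated /
dated trees) or substitutions per site (trees inferred here); callers are
expected to know which.  Internal node labels, when parseable as floats,
are treated as clade supports in [0, 1].

The neighbor-joining implementation is deliberately written out rather
than delegated, so tie-breaking is deterministic (lexicographic by the
smallest tip label of each cluster): inference must be reproducible
bit-for-bit under a fixed seed.  Dendropy remains the substrate for
Newick parsing/serialization, rerooting and pruning.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from ._coalescent import (
    LNode,
    bipartitions,
    branch_score_light,
    rf_distance_light,
)

__all__ = [
    "NewickParseError",
    "read_newick",
    "write_newick",
    "node_support",
    "infer_gene_tree",
    "bootstrap_support",
    "rf_distance",
    "branch_score_distance",
    "prune",
    "to_light",
    "from_light",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the parse position."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree from a string (rooted interpretation).

    Internal node labels (e.g. support values) are preserved as node
    labels; underscores are not converted to spaces.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        pos = f" (line {line}, column {col})" if line is not None else ""
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise NewickParseError("malformed Newick: no tips found")
    return tree


def write_newick(tree: dendropy.Tree, digits: int = 12) -> str:
    """Serialize to Newick; numbers at ``digits`` significant figures."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{digits}g",
    ).strip()


def node_support(node: dendropy.Node) -> float | None:
    """Clade support parsed from the internal node label, if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Conversions between dendropy trees and the light representation


def to_light(tree: dendropy.Tree) -> LNode:
    """Convert to the light node form; ages = max tip depth - node depth."""
    depths = {}

    def down(node, d):
        depths[node] = d
        for c in node.child_nodes():
            el = c.edge.length or 0.0
            down(c, d + el)

    down(tree.seed_node, 0.0)
    height = max(depths[l] for l in tree.leaf_node_iter())

    def build(node):
        age = height - depths[node]
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            return LNode(label=label, age=age)
        return LNode(age=age, children=[build(c) for c in node.child_nodes()])

    return build(tree.seed_node)


def from_light(root: LNode) -> dendropy.Tree:
    """Convert a light tree (ages in years) to a dendropy tree."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(lnode, dnode):
        for c in lnode.children:
            child = dnode.new_child()
            child.edge.length = max(lnode.age - c.age, 0.0)
            if c.children:
                build(c, child)
            else:
                child.taxon = taxa.require_taxon(label=c.label)

    if not root.children:  # single-tip tree
        tree.seed_node.taxon = taxa.require_taxon(label=root.label)
    else:
        build(root, tree.seed_node)
    return tree


# ---------------------------------------------------------------------------
# Pairwise distances

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequences(alignment) -> tuple[list[str], np.ndarray]:
    """Encode an alignment (dict or (label, seq) pairs) as int8 codes.

    A, C, G, T -> 0..3; anything else (N, gaps, ambiguity codes) -> -1.
    """
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = list(alignment)
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels in alignment")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in length")
    mat = np.full((len(items), lengths.pop()), -1, dtype=np.int8)
    for i, (_, seq) in enumerate(items):
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for base, code in _CODE.items():
            mat[i, arr == ord(base)] = code
    return labels, mat


def hky_corrected_distance(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """HKY-corrected distance between two coded sequences.

    Uses the Tamura-Nei closed form (which contains HKY as a special
    case), with empirical base frequencies from the pair.  Returns
    ``(distance, fell_back)``: when the correction is undefined
    (saturation, log of a non-positive number) the raw p-distance is
    returned instead with ``fell_back=True``.
    """
    ok = (x >= 0) & (y >= 0)
    n = int(ok.sum())
    if n == 0:
        return 0.0, True
    xs, ys = x[ok], y[ok]
    counts = np.bincount(np.concatenate([xs, ys]), minlength=4).astype(float)
    freqs = counts / counts.sum()
    pA, pC, pG, pT = freqs
    pR, pY = pA + pG, pC + pT
    diff = xs != ys
    pdist = float(diff.mean())
    if pdist == 0.0:
        return 0.0, False
    ts1 = float((((xs == 0) & (ys == 2)) | ((xs == 2) & (ys == 0))).mean())  # A<->G
    ts2 = float((((xs == 1) & (ys == 3)) | ((xs == 3) & (ys == 1))).mean())  # C<->T
    tv = pdist - ts1 - ts2
    if min(pA, pC, pG, pT) <= 0 or pR <= 0 or pY <= 0:
        return pdist, True
    w1 = 1.0 - pR * ts1 / (2.0 * pA * pG) - tv / (2.0 * pR)
    w2 = 1.0 - pY * ts2 / (2.0 * pC * pT) - tv / (2.0 * pY)
    w3 = 1.0 - tv / (2.0 * pR * pY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return pdist, True
    d = (
        -2.0 * pA * pG / pR * math.log(w1)
        - 2.0 * pC * pT / pY * math.log(w2)
        - 2.0 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY) * math.log(w3)
    )
    return max(d, 0.0), False


def distance_matrix(alignment):
    """Labels and pairwise HKY-corrected distance matrix for an alignment."""
    labels, mat = encode_sequences(alignment)
    n = len(labels)
    D = np.zeros((n, n))
    fallback_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            d, fell = hky_corrected_distance(mat[i], mat[j])
            D[i, j] = D[j, i] = d
            if fell and d > 0:
                fallback_pairs.append((labels[i], labels[j]))
    return labels, D, fallback_pairs


# ---------------------------------------------------------------------------
# Neighbor joining


def _neighbor_joining(labels, D):
    """NJ with deterministic tie-breaking; returns a light tree.

    Clusters are joined by minimum Q; ties are broken by the
    lexicographically smallest (min-tip-label, min-tip-label) pair.
    Negative branch lengths are clamped to zero.  The final two clusters
    are joined at an arbitrary root (callers midpoint-reroot).
    """
    n = len(labels)
    nodes = [LNode(label=lab) for lab in labels]
    keys = list(labels)  # smallest tip label within each cluster
    D = D.copy().astype(float)
    active = list(range(n))
    # store branch lengths on the light nodes via meta (years field unused)
    blen = {id(nd): 0.0 for nd in nodes}

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                ka, kb = keys[active[a]], keys[active[b]]
                tie = tuple(sorted((ka, kb)))
                cand = (q, tie, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        ia, ib = active[a], active[b]
        dab = D[ia, ib]
        va = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2)) if m > 2 else 0.5 * dab
        va = min(max(va, 0.0), dab) if dab > 0 else 0.0
        vb = max(dab - va, 0.0)
        new = LNode(children=[nodes[ia], nodes[ib]])
        blen[id(nodes[ia])] = va
        blen[id(nodes[ib])] = vb
        # distances from the new cluster to the rest
        newrow = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (ia, ib):
                continue
            newrow[c] = max(0.5 * (D[ia, c] + D[ib, c] - dab), 0.0)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(new)
        keys.append(min(keys[ia], keys[ib]))
        blen[id(new)] = 0.0
        active = [c for c in active if c not in (ia, ib)] + [len(nodes) - 1]

    ia, ib = active
    root = LNode(children=[nodes[ia], nodes[ib]])
    blen[id(nodes[ia])] = 0.5 * D[ia, ib]
    blen[id(nodes[ib])] = 0.5 * D[ia, ib]

    # convert stored branch lengths into ages (ages only need to be
    # consistent: from_light uses parent.age - child.age as edge length)
    def set_ages(node, age_above):
        node.age = age_above - blen[id(node)]
        for c in node.children:
            set_ages(c, node.age)

    # use a tall starting age so ages stay positive (values are relative)
    total = float(D.max() * 4 + 1.0)
    root.age = total
    for c in root.children:
        set_ages(c, total)
    return root


def infer_gene_tree(alignment, method: str = "NJ_HKY", outgroup: str | None = None):
    """Neighbor-joining gene tree from aligned sequences.

    Distances are HKY-corrected (TN93 closed form); saturated pairs fall
    back to p-distance and are listed in ``tree.saturated_pairs``.  The
    tree is midpoint-rooted unless ``outgroup`` names a tip.
    """
    if method != "NJ_HKY":
        raise ValueError(f"unknown inference method: {method}")
    labels, D, fallback = distance_matrix(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences to infer a tree")
    light = _neighbor_joining(labels, D)
    tree = from_light(light)
    if outgroup is not None:
        tips = {l.taxon.label: l for l in tree.leaf_node_iter()}
        if outgroup not in tips:
            raise ValueError(f"outgroup {outgroup!r} not in alignment")
        tree.to_outgroup_position(tips[outgroup], update_bipartitions=False)
    else:
        if any(e.length for e in tree.preorder_edge_iter() if e.length):
            tree.reroot_at_midpoint(update_bipartitions=False)
    tree.saturated_pairs = fallback
    return tree


def bootstrap_support(alignment, n_reps: int = 100, seed: int | None = None):
    """Site-resampling bootstrap proportions on the NJ tree.

    Returns the tree inferred from the full alignment with internal node
    labels set to the fraction of bootstrap replicates containing each
    bipartition (restricted to non-trivial unrooted bipartitions).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = list(alignment)
    labels = [k for k, _ in items]
    L = len(items[0][1])
    base = infer_gene_tree(items)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_aln = [(k, "".join(s[c] for c in cols)) for k, s in items]
        rep = infer_gene_tree(rep_aln)
        for bp in bipartitions(to_light(rep)):
            counts[bp] = counts.get(bp, 0) + 1
    shared = set(labels)
    ref = min(shared)
    ntax = len(shared)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node is base.seed_node:
            continue
        s = {l.taxon.label for l in node.leaf_iter()}
        if not (1 < len(s) < ntax - 1):
            continue
        side = frozenset(s if ref not in s else shared - s)
        node.label = f"{counts.get(side, 0) / n_reps:g}"
    return base


# ---------------------------------------------------------------------------
# Comparison and pruning


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted RF bipartition distance on the shared-taxon restriction."""
    l1, l2 = to_light(t1), to_light(t2)
    shared = set(n.label for n in l1.leaves()) & set(n.label for n in l2.leaves())
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared tips between trees")
    return rf_distance_light(l1, l2)


def branch_score_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Branch-score (Kuhner-Felsenstein) distance on shared taxa.

    The square root of the summed squared differences in edge length per
    bipartition (0 where a bipartition is absent), after restricting both
    trees to their shared tips.  Continuous where RF is integer-valued, so
    Monte-Carlo tests built on it are not limited by atoms.
    """
    l1, l2 = to_light(t1), to_light(t2)
    shared = set(n.label for n in l1.leaves()) & set(n.label for n in l2.leaves())
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared tips between trees")
    ident = {s: s for s in shared}
    return branch_score_light(l1, l2, ident, ident)


def prune(tree: dendropy.Tree, tips_to_remove) -> dendropy.Tree:
    """Remove tips, suppress unifurcations, and sum merged branch lengths."""
    tips_to_remove = set(tips_to_remove)
    present = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = tips_to_remove - present
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    if tips_to_remove >= present:
        raise ValueError("cannot remove all tips")
    out = dendropy.Tree(tree)
    taxa = [t for t in out.taxon_namespace if t.label in tips_to_remove]
    out.prune_taxa(taxa, suppress_unifurcations=True)
    out.purge_taxon_namespace()
    return out
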