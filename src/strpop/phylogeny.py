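"""Neighbor-Joining trees from distance matrices, with bootstrap over loci.

The Saitou-Nei agglomeration is implemented directly so that its two
underdetermined details are pinned down reproducibly: ties in the
Q-criterion are broken by the lexicographically lowest index pair, and a
negative branch length is clamped to zero with the deficit transferred
to its sibling branch (the raw value is kept on the node as
``raw_length``).  NJ recovers the generating tree exactly on additive
matrices, which is the main correctness property the tests exercise.

Bootstrap support follows the published pipeline: loci are resampled
with replacement, the distance matrix and tree are rebuilt per
replicate, and each internal edge of the full-data tree is annotated
with the percentage of replicates containing the same bipartition.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .distance import da_matrix
from .str_data import PopulationSet

__all__ = ["neighbor_joining", "bootstrap_tree", "bipartitions",
           "has_bipartition", "support_values"]


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # clamp a negative estimate to 0, moving the deficit to the sibling so
    # the path length through the new node is preserved
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _attach(child: TreeNode, length: float, raw: float) -> TreeNode:
    child.length = float(length)
    child.raw_length = float(raw)
    return child


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build the Saitou-Nei NJ tree for a labelled distance matrix.

    The result is an unrooted tree serialized with its basal trifurcation
    as the root node (arbitrary but stable).  Requires >= 3 labels and a
    symmetric matrix (the readers symmetrize on input).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    nodes = [TreeNode(name=name) for name in ids]

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        iu = np.triu_indices(r, k=1)
        qmin = q[iu].min()
        # lexicographically lowest (i, j) among the minimizers
        i = j = -1
        for a in range(r):
            hit = np.flatnonzero(q[a, a + 1:] == qmin)
            if hit.size:
                i, j = a, a + 1 + int(hit[0])
                break
        dij = d[i, j]
        li_raw = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj_raw = dij - li_raw
        li, lj = _clamp_pair(li_raw, lj_raw)
        parent = TreeNode(children=[_attach(nodes[i], li, li_raw),
                                    _attach(nodes[j], lj, lj_raw)])
        # distances from the new node to every remaining node
        keep = [x for x in range(r) if x not in (i, j)]
        du = 0.5 * (d[i, keep] + d[j, keep] - dij)
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = du
        d[:-1, -1] = du
        nodes = [nodes[x] for x in keep] + [parent]

    # final trifurcation: closed-form lengths l_i = (d_ij + d_ik - d_jk) / 2
    (a, b, c) = (0, 1, 2)
    raw = [0.5 * (d[a, b] + d[a, c] - d[b, c]),
           0.5 * (d[a, b] + d[b, c] - d[a, c]),
           0.5 * (d[a, c] + d[b, c] - d[a, b])]
    root = TreeNode(children=[_attach(nodes[k], max(raw[k], 0.0), raw[k])
                              for k in range(3)])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Nontrivial leaf bipartitions of an unrooted tree, one per internal
    edge, canonicalized as the side *not* containing the alphabetically
    first leaf (so the encoding is invariant to leaf ordering/rooting)."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def has_bipartition(tree: TreeNode, side) -> bool:
    """True if some internal edge splits the leaves into *side* vs the
    rest (either orientation of the split matches)."""
    leaves = frozenset(t.name for t in tree.tips())
    side = frozenset(side)
    if not side <= leaves:
        raise ValueError("side contains labels not in the tree")
    ref = min(leaves)
    if ref in side:
        side = leaves - side
    return side in bipartitions(tree)


def support_values(tree: TreeNode) -> dict[frozenset, int]:
    """Bipartition -> integer support, read off the internal node labels."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = {}
    for node in tree.non_tips(include_self=False):
        if node.name is None:
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        out[side] = int(node.name)
    return out


def bootstrap_tree(pops: PopulationSet, metric: str = "da",
                   reps: int = 1000, seed: int = 1) -> TreeNode:
    """NJ tree of the full data with bootstrap-over-loci supports.

    Each replicate resamples the locus panel with replacement, rebuilds
    the distance matrix and NJ tree, and each internal edge of the
    full-data tree is labelled with the percentage (0-100, rounded) of
    replicates containing its bipartition.
    """
    if metric != "da":
        raise ValueError("bootstrap is defined here for the DA metric")
    loci = pops.loci
    if len(pops.names) < 3:
        raise ValueError("need at least 3 populations")
    if len(loci) < 2:
        raise ValueError("bootstrap over loci needs at least 2 loci")
    full = neighbor_joining(da_matrix(pops))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(full)}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        draw = rng.integers(0, len(loci), size=len(loci))
        sub = pops.subset_loci([loci[i] for i in draw])
        rep_bps = bipartitions(neighbor_joining(da_matrix(sub)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = frozenset(t.name for t in full.tips())
    ref = min(leaves)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if side in counts:
            node.name = str(int(round(100.0 * counts[side] / reps)))
    return full
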