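"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (exhaustive
pairing enumeration, term-by-term formulas, tree-path arithmetic) kept
separate from the library code they check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from strpop import AlleleLabel, GenotypeTable, load_gorkha_frequencies


@pytest.fixture(scope="session")
def gorkha():
    return load_gorkha_frequencies()


def make_table(genotype_strings: dict[str, list[str | None]]) -> GenotypeTable:
    """Build a GenotypeTable from {locus: ["8/9", "11", None, ...]}."""
    loci = list(genotype_strings)
    n = len(next(iter(genotype_strings.values())))
    sample_ids = [f"S{i + 1}" for i in range(n)]
    calls = {}
    for locus, cells in genotype_strings.items():
        for s, cell in zip(sample_ids, cells):
            if cell is None:
                calls[(s, locus)] = None
            else:
                parts = cell.split("/")
                a = AlleleLabel.parse(parts[0])
                b = AlleleLabel.parse(parts[-1])
                calls[(s, locus)] = (a, b) if a <= b else (b, a)
    return GenotypeTable(sample_ids, loci, calls)


@pytest.fixture
def tiny_table():
    # 3 individuals, 2 loci, one missing call
    return make_table({
        "L1": ["8/9", "8/8", "9/10"],
        "L2": ["11/12", None, "12/12"],
    })


# ---------------------------------------------------------------------------
# exhaustive perfect-matching oracle for the exact HWE test

def _pairings(items: tuple[int, ...]):
    if not items:
        yield ()
        return
    first = items[0]
    for i in range(1, len(items)):
        rest = items[1:i] + items[i + 1:]
        for rest_pairs in _pairings(rest):
            yield ((first, items[i]),) + rest_pairs


def hwe_p_by_matching(genotypes: dict[tuple[int, int], int]) -> float:
    """Exact HWE p-value by enumerating every perfect matching of the
    labelled gene copies — feasible up to ~6 individuals."""
    counts = Counter()
    for (i, j), c in genotypes.items():
        counts[i] += c
        counts[j] += c
    copies = tuple(a for a, c in sorted(counts.items()) for _ in range(c))
    arrays = Counter()
    for pairing in _pairings(copies):
        key = tuple(sorted(tuple(sorted(p)) for p in pairing))
        arrays[key] += 1
    total = sum(arrays.values())
    obs = tuple(sorted(k for k, c in genotypes.items() for _ in range(c)))
    p_obs = arrays[obs] / total
    return sum(c / total for c in arrays.values() if c / total <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# random additive trees (ground truth for NJ exactness)

def random_additive_tree(n_leaves: int, rng: np.random.Generator
                         ) -> tuple[TreeNode, DistanceMatrix]:
    """A random unrooted binary tree with positive branch lengths and its
    exact leaf-to-leaf path-length matrix."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = float(rng.uniform(0.1, 2.0))
    tree = TreeNode(children=nodes)
    dm = tree.tip_tip_distances()
    order = sorted(dm.ids)
    return tree, dm.filter(order)


def two_clade_popset(rng: np.random.Generator, n_loci: int = 12,
                     f_between: float = 0.2, f_within: float = 0.01,
                     n: int = 200):
    """Two 2-population clades drifted apart: ancestral -> clade
    frequencies (strong drift) -> population frequencies (weak drift)."""
    from strpop.str_data import AlleleFrequencyTable, PopulationSet
    from strpop.synthetic_data import dirichlet_frequencies

    def bn_draw(freqs, f):
        alleles = list(freqs)
        p = np.array([freqs[a] for a in alleles])
        q = rng.dirichlet(p * (1 - f) / f)
        q = np.clip(q, 1e-9, None)
        return dict(zip(alleles, q / q.sum()))

    loci = [f"L{i}" for i in range(n_loci)]
    pops = {name: {} for name in ("a1", "a2", "b1", "b2")}
    for locus in loci:
        anc = dirichlet_frequencies(5, 1.0, rng)
        clade_a = bn_draw(anc, f_between)
        clade_b = bn_draw(anc, f_between)
        pops["a1"][locus] = bn_draw(clade_a, f_within)
        pops["a2"][locus] = bn_draw(clade_a, f_within)
        pops["b1"][locus] = bn_draw(clade_b, f_within)
        pops["b2"][locus] = bn_draw(clade_b, f_within)
    return PopulationSet({
        name: AlleleFrequencyTable(loci, {locus: n for locus in loci}, by_locus)
        for name, by_locus in pops.items()})


def bipartition_set(tree: TreeNode) -> set[frozenset]:
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out
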