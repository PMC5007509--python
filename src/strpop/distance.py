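"""Between-population distances from STR allele frequencies.

Two measures are provided.  Nei's DA distance,

    DA = 1 - (1/L) * sum_l sum_i sqrt(x_li * y_li),

averages the across-allele geometric overlap of two frequency vectors
over L loci; it is the distance behind the published dendrograms.
Weir & Cockerham's theta estimates Fst from variance components a
(between populations), b (between individuals within populations) and c
(within individuals), summed over alleles and loci before taking the
ratio; it can be slightly negative when populations are effectively
undifferentiated.

Inputs here are allele *frequencies* plus sample sizes, the situation of
published compilations: copy counts are reconstructed as round(freq*2n),
and the within-individual heterozygosity entering b and c uses its
random-mating expectation 2p(1-p) — the frequency-only approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .str_data import PopulationSet

__all__ = ["nei_da", "da_matrix", "wc_fst", "fst_matrix",
           "fst_permutation_p", "FstResult"]


def nei_da(pops: PopulationSet, a: str, b: str) -> float:
    """Nei's DA distance between populations *a* and *b* over their
    shared loci (allele domains unioned; absent alleles contribute 0)."""
    for name in (a, b):
        if name not in pops.populations:
            raise KeyError(f"unknown population {name!r}")
    loci = pops.loci
    if not loci:
        raise ValueError("no shared loci")
    overlap = 0.0
    for locus in loci:
        _, mat = pops.frequency_matrix(locus, names=[a, b])
        overlap += float(np.sum(np.sqrt(mat[0] * mat[1])))
    return 1.0 - overlap / len(loci)


def da_matrix(pops: PopulationSet) -> DistanceMatrix:
    names = pops.names
    loci = pops.loci
    k = len(names)
    overlap = np.zeros((k, k))
    for locus in loci:
        _, mat = pops.frequency_matrix(locus, names=names)
        root = np.sqrt(mat)
        overlap += root @ root.T
    d = 1.0 - overlap / len(loci)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(np.clip(d, 0.0, None), ids=names)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (two populations)

def _theta_components(c1: np.ndarray, c2: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Variance components for one locus from allele copy-count vectors.

    ``c1``/``c2`` may be 1-D (alleles,) or batched 2-D (reps, alleles);
    returns (sum_a, sum_abc) over alleles per batch entry.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = c1.sum(axis=-1, keepdims=True) / 2.0   # individuals per population
    n2 = c2.sum(axis=-1, keepdims=True) / 2.0
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("each population needs at least one individual")
    p1 = c1 / (2.0 * n1)
    p2 = c2 / (2.0 * n2)
    nbar = (n1 + n2) / 2.0
    nc = 2.0 * nbar - (n1 ** 2 + n2 ** 2) / (2.0 * nbar)
    pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    # within-individual heterozygosity: random-mating expectation 2p(1-p)
    h1 = 2.0 * p1 * (1.0 - p1)
    h2 = 2.0 * p2 * (1.0 - p2)
    hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - s2 / 2.0 - (2.0 * nbar - 1.0)
                                 / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a.sum(axis=-1), (a + b + c).sum(axis=-1)


@dataclass
class FstResult:
    """Weir-Cockerham theta per locus and combined across loci."""

    per_locus: dict[str, float]
    theta: float


def _count_matrices(pops: PopulationSet, a: str, b: str
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for locus in pops.loci:
        domain, _ = pops.frequency_matrix(locus, names=[a, b])
        ca = np.zeros(len(domain))
        cb = np.zeros(len(domain))
        index = {al: i for i, al in enumerate(domain)}
        for al, cnt in pops.populations[a].counts(locus).items():
            ca[index[al]] = cnt
        for al, cnt in pops.populations[b].counts(locus).items():
            cb[index[al]] = cnt
        out[locus] = (ca, cb)
    return out


def wc_fst(pops: PopulationSet, a: str, b: str) -> FstResult:
    """Pairwise Weir-Cockerham theta between two populations, per locus and
    multi-locus (ratio of summed components).  Negative estimates are
    reported as computed, not truncated."""
    counts = _count_matrices(pops, a, b)
    if all(ca.sum() == 0 for ca, _ in counts.values()) or \
       all(cb.sum() == 0 for _, cb in counts.values()):
        raise ValueError("a population has zero gene copies at every locus")
    per_locus: dict[str, float] = {}
    num = den = 0.0
    for locus, (ca, cb) in counts.items():
        sa, sabc = _theta_components(ca, cb)
        per_locus[locus] = float(sa / sabc) if sabc != 0 else 0.0
        num += float(sa)
        den += float(sabc)
    return FstResult(per_locus=per_locus, theta=num / den if den else 0.0)


def fst_matrix(pops: PopulationSet):
    """Pairwise multi-locus theta for every population pair, as a labelled
    pandas DataFrame (thetas may be negative, so this is not a metric)."""
    import pandas as pd

    names = pops.names
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            t = wc_fst(pops, a, names[j]).theta
            mat[i, j] = mat[j, i] = t
    return pd.DataFrame(mat, index=names, columns=names)


def fst_permutation_p(pops: PopulationSet, a: str, b: str,
                      reps: int = 10_000, seed: int = 1) -> dict[str, float]:
    """Locus-wise permutation p-values for differentiation.

    The 2nA + 2nB gene copies at a locus are pooled and reshuffled into
    the original group sizes; p = (1 + #{theta* >= theta_obs}) / (1 + reps),
    one-sided, since differentiation only inflates theta.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _count_matrices(pops, a, b)
    pvals: dict[str, float] = {}
    for locus, (ca, cb) in counts.items():
        k = len(ca)
        sa, sabc = _theta_components(ca, cb)
        theta_obs = float(sa / sabc) if sabc != 0 else 0.0
        pool = np.repeat(np.arange(k), (ca + cb).astype(int))
        size_a = int(ca.sum())
        hits = 0
        done = 0
        chunk = 5_000
        while done < reps:
            r = min(chunk, reps - done)
            perm = rng.permuted(np.tile(pool, (r, 1)), axis=1)
            ga = perm[:, :size_a]
            gb = perm[:, size_a:]
            offs = np.arange(r)[:, None] * k
            ca_r = np.bincount((ga + offs).ravel(), minlength=r * k).reshape(r, k)
            cb_r = np.bincount((gb + offs).ravel(), minlength=r * k).reshape(r, k)
            sa_r, sabc_r = _theta_components(ca_r, cb_r)
            with np.errstate(divide="ignore", invalid="ignore"):
                theta_r = np.where(sabc_r != 0, sa_r / sabc_r, 0.0)
            hits += int(np.sum(theta_r >= theta_obs - 1e-12))
            done += r
        pvals[locus] = (1 + hits) / (1 + reps)
    return pvals
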