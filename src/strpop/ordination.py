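"""Low-dimensional embeddings of populations.

Two routes are exposed because published STR ordinations are made both
ways: classical metric scaling (PCoA) of a genetic-distance matrix, and
plain PCA of the populations-by-alleles frequency table.  Axis signs are
fixed (largest-magnitude entry positive) so repeated runs and platforms
agree exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .str_data import PopulationSet

__all__ = ["pcoa", "pca_frequencies", "Ordination"]


@dataclass
class Ordination:
    """Coordinates (labels x axes) plus the eigenvalue spectrum and the
    per-axis explained-variance fractions."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def pcoa(dm: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical scaling of a distance matrix: double-center -D^2/2,
    eigendecompose, scale eigenvectors by sqrt(eigenvalue).

    Axes are ordered by descending eigenvalue; axes with non-positive
    eigenvalues are dropped (a warning is issued if that truncates the
    request below *k*).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = int(np.sum(eig > 1e-12))
    if pos < k:
        warnings.warn(f"only {pos} positive eigenvalues; returning {pos} axes "
                      f"instead of {k}")
    take = min(k, pos) if pos else 0
    coords = _fix_signs(res.samples.to_numpy()[:, :take].copy())
    cols = [f"PCo{i + 1}" for i in range(take)]
    total = float(np.sum(eig[eig > 0])) or 1.0
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eig,
        proportion_explained=np.clip(eig[:take], 0, None) / total,
    )


def pca_frequencies(pops: PopulationSet, k: int = 2) -> Ordination:
    """PCA of the populations x (locus, allele) frequency matrix.

    Columns are mean-centered; scores come from the SVD of the centered
    matrix, deterministic up to the sign convention applied here.
    """
    names = pops.names
    if len(names) < 2:
        raise ValueError("need at least 2 populations")
    blocks = []
    for locus in pops.loci:
        _, mat = pops.frequency_matrix(locus, names=names)
        blocks.append(mat)
    x = np.hstack(blocks)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s ** 2
    total = float(var.sum()) or 1.0
    nz = int(np.sum(s > 1e-12 * max(s[0], 1.0)))
    take = min(k, nz)
    scores = _fix_signs((u[:, :take] * s[:take]).copy())
    cols = [f"PC{i + 1}" for i in range(take)]
    return Ordination(
        coordinates=pd.DataFrame(scores, index=names, columns=cols),
        eigenvalues=var / max(len(names) - 1, 1),
        proportion_explained=var[:take] / total,
    )
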