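"""Seeded generators emulating the study's data-generating assumptions.

No raw STR genotypes are published for studies of this kind, so every
stage of the pipeline is exercised on simulated data instead: random
mating within a population (the null every HWE test assumes), excess
homozygosity parameterized by an inbreeding coefficient F_is (the
alternative the tests must detect), and sets of populations drifted
apart from a common ancestor to a target differentiation F_st under the
Balding-Nichols Dirichlet model, whose expected Fst equals F — giving
estimator-recovery experiments a quantitative target.

Defaults mirror the study scale: 15 loci with the allele counts observed
in the published panel, 98 individuals per population.  All generators
are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .str_data import (AlleleLabel, AlleleFrequencyTable, GenotypeTable,
                       PopulationSet, GORKHA_LOCI)

__all__ = ["SimulationConfig", "sample_hwe_population",
           "sample_inbred_population", "sample_balding_nichols",
           "dirichlet_frequencies", "GORKHA_ALLELE_COUNTS"]

#: observed number of alleles per locus in the published 15-locus panel
GORKHA_ALLELE_COUNTS = (10, 11, 9, 7, 7, 6, 7, 7, 11, 13, 8, 5, 14, 7, 16)


@dataclass
class SimulationConfig:
    """Knobs of the drift/inbreeding simulators.

    ``alleles_per_locus`` may be a single int or one count per locus.
    ``ancestral`` optionally fixes the ancestral frequency vectors
    (list of dicts allele->freq, one per locus); otherwise they are drawn
    from a symmetric Dirichlet with the given concentration.
    """

    loci: tuple[str, ...] = GORKHA_LOCI
    alleles_per_locus: int | tuple[int, ...] = GORKHA_ALLELE_COUNTS
    ancestral: list[dict[AlleleLabel, float]] | None = None
    n: int = 98
    f_is: float = 0.0
    f_st: float = 0.0
    n_pops: int = 2
    dirichlet_concentration: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_is <= 1.0):
            raise ValueError("f_is must be in [0, 1]")
        if not (0.0 <= self.f_st < 1.0):
            raise ValueError("f_st must be in [0, 1)")
        if self.n < 1 or self.n_pops < 1:
            raise ValueError("n and n_pops must be positive")

    def allele_counts(self) -> tuple[int, ...]:
        if isinstance(self.alleles_per_locus, int):
            return (self.alleles_per_locus,) * len(self.loci)
        if len(self.alleles_per_locus) != len(self.loci):
            raise ValueError("alleles_per_locus length != number of loci")
        return tuple(self.alleles_per_locus)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _domain(k: int) -> list[AlleleLabel]:
    # arbitrary but realistic labels: consecutive repeat counts from 6
    return [AlleleLabel(6 + i) for i in range(k)]


def dirichlet_frequencies(k: int, concentration: float,
                          rng: np.random.Generator) -> dict[AlleleLabel, float]:
    """One locus's frequency vector from a symmetric Dirichlet."""
    p = rng.dirichlet(np.full(k, concentration))
    p = np.clip(p, 1e-6, None)
    p /= p.sum()
    return dict(zip(_domain(k), p))


def _draw_genotypes(freq_by_locus: dict[str, dict[AlleleLabel, float]], n: int,
                    f_is: float, rng: np.random.Generator) -> GenotypeTable:
    sample_ids = [f"S{i + 1}" for i in range(n)]
    calls = {}
    for locus, freqs in freq_by_locus.items():
        alleles = list(freqs)
        p = np.asarray([freqs[a] for a in alleles], dtype=float)
        p = p / p.sum()
        first = rng.choice(len(alleles), size=n, p=p)
        second = rng.choice(len(alleles), size=n, p=p)
        if f_is > 0:
            forced = rng.random(n) < f_is
            second = np.where(forced, first, second)
        for s, i1, i2 in zip(sample_ids, first, second):
            a, b = alleles[i1], alleles[i2]
            calls[(s, locus)] = (a, b) if a <= b else (b, a)
    return GenotypeTable(sample_ids, list(freq_by_locus), calls)


def sample_hwe_population(freq_by_locus: dict[str, dict[AlleleLabel, float]],
                          n: int, seed: int | np.random.Generator = 1
                          ) -> GenotypeTable:
    """Genotypes under random mating: each individual's two alleles are
    independent draws from the locus frequencies."""
    return _draw_genotypes(freq_by_locus, n, 0.0, _as_rng(seed))


def sample_inbred_population(freq_by_locus: dict[str, dict[AlleleLabel, float]],
                             n: int, f_is: float,
                             seed: int | np.random.Generator = 1
                             ) -> GenotypeTable:
    """Genotypes with excess homozygosity: with probability ``f_is`` an
    individual is made homozygous for a single drawn allele, otherwise it
    is a random-mating draw.  Expected Hobs = (1 - F_is)(1 - sum p^2)."""
    if not (0.0 <= f_is <= 1.0):
        raise ValueError("f_is must be in [0, 1]")
    return _draw_genotypes(freq_by_locus, n, f_is, _as_rng(seed))


def sample_balding_nichols(config: SimulationConfig
                           ) -> tuple[PopulationSet, dict[str, GenotypeTable]]:
    """Populations drifted from a shared ancestor to target Fst.

    Per locus, each population's frequency vector is drawn from
    Dirichlet(p * (1 - F) / F) around the ancestral vector p (F = 0
    copies the ancestor exactly); genotypes are then random-mating draws
    within populations, with optional within-population inbreeding.
    Returns the frequency tables (as estimated from the drawn genotypes'
    true per-population frequencies) together with the genotype tables.
    """
    rng = _as_rng(config.seed)
    counts = config.allele_counts()
    loci = list(config.loci)
    if config.ancestral is not None:
        if len(config.ancestral) != len(loci):
            raise ValueError("ancestral needs one frequency map per locus")
        ancestral = [dict(f) for f in config.ancestral]
    else:
        ancestral = [dirichlet_frequencies(k, config.dirichlet_concentration, rng)
                     for k in counts]
    names = [f"pop{i + 1}" for i in range(config.n_pops)]
    tables: dict[str, AlleleFrequencyTable] = {}
    genotypes: dict[str, GenotypeTable] = {}
    f = config.f_st
    for name in names:
        freq_by_locus: dict[str, dict[AlleleLabel, float]] = {}
        for locus, anc in zip(loci, ancestral):
            alleles = list(anc)
            p = np.asarray([anc[a] for a in alleles], dtype=float)
            if f > 0:
                drawn = rng.dirichlet(p * (1.0 - f) / f)
                drawn = np.clip(drawn, 1e-9, None)
                drawn /= drawn.sum()
            else:
                drawn = p
            freq_by_locus[locus] = dict(zip(alleles, drawn))
        g = _draw_genotypes(freq_by_locus, config.n, config.f_is, rng)
        genotypes[name] = g
        tables[name] = AlleleFrequencyTable.from_genotypes(g)
    return PopulationSet(tables), genotypes
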