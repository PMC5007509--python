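"""Per-locus and combined forensic parameters for STR panels.

Implements the standard forensic summary of a genotyped STR locus:
observed and (bias-corrected) expected heterozygosity, polymorphism
information content (Botstein), matching probability over observed
genotype classes with its complement the power of discrimination, power
of exclusion and typical paternity index as functions of observed
heterozygosity, and the across-locus combinations CPD, CPE and mean Pm.

Conventions follow the PowerStats spreadsheet lineage used throughout
the forensic-genetics literature: Pm is computed from *observed*
genotype-class frequencies (not Hardy-Weinberg expected products), and
Hexp carries Nei's small-sample factor 2n/(2n-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .str_data import AlleleLabel, GenotypeTable, LocusSummary

__all__ = [
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "match_probability",
    "expected_match_probability",
    "power_of_discrimination",
    "power_of_exclusion",
    "paternity_index",
    "snap_to_count",
    "combined_statistics",
    "summarize",
    "ForensicReport",
]


def allele_frequencies(g: GenotypeTable, locus: str
                       ) -> tuple[dict[AlleleLabel, float], int]:
    """Allele frequencies at *locus* over 2n gene copies, with n the
    number of non-missing individuals (pairwise deletion)."""
    calls = g.genotypes_at(locus)
    if not calls:
        raise ValueError(f"no non-missing calls at locus {locus}")
    counts: dict[AlleleLabel, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    n = len(calls)
    total = 2 * n
    return {a: c / total for a, c in sorted(counts.items())}, n


def observed_heterozygosity(g: GenotypeTable, locus: str) -> float:
    calls = g.genotypes_at(locus)
    if not calls:
        raise ValueError(f"no non-missing calls at locus {locus}")
    return sum(1 for a, b in calls if a != b) / len(calls)


def expected_heterozygosity(freqs: Mapping, n: int, unbiased: bool = True) -> float:
    """Expected heterozygosity 1 - sum(p_i^2), by default with Nei's
    small-sample correction 2n/(2n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s2 = sum(p * p for p in freqs.values())
    h = 1.0 - s2
    if unbiased:
        h *= (2 * n) / (2 * n - 1)
    return min(h, 1.0)


def pic(freqs: Mapping) -> float:
    """Polymorphism information content (Botstein et al. formula):
    1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4."""
    p = np.asarray(list(freqs.values()), dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 1.0 - s2 - s2 * s2 + s4


def match_probability(g: GenotypeTable, locus: str) -> float:
    """Matching probability: sum of squared *observed* genotype-class
    frequencies at the locus."""
    calls = g.genotypes_at(locus)
    if not calls:
        raise ValueError(f"no non-missing calls at locus {locus}")
    classes: dict = {}
    for call in calls:
        classes[call] = classes.get(call, 0) + 1
    n = len(calls)
    return sum((c / n) ** 2 for c in classes.values())


def expected_match_probability(freqs: Mapping) -> float:
    """Pm under random mating: sum over genotypes of the squared HWE
    genotype frequency.  Provided for frequency-only input; clearly
    distinct from the observed-class Pm used in genotype summaries."""
    p = np.asarray(list(freqs.values()), dtype=float)
    homo = p ** 2
    outer = np.outer(p, p)
    het = 2.0 * outer[np.triu_indices(len(p), k=1)]
    return float(np.sum(homo ** 2) + np.sum(het ** 2))


def power_of_discrimination(pm: float) -> float:
    return 1.0 - pm


def power_of_exclusion(h_obs: float) -> float:
    """PE = h^2 (1 - 2 h H^2) with h observed heterozygosity, H = 1 - h."""
    if not (0.0 <= h_obs <= 1.0):
        raise ValueError("h_obs must be in [0, 1]")
    h = h_obs
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def paternity_index(h_obs: float) -> float:
    """Typical paternity index PI = 1 / (2 (1 - h))."""
    if not (0.0 <= h_obs <= 1.0):
        raise ValueError("h_obs must be in [0, 1]")
    if h_obs == 1.0:
        raise ValueError("paternity index undefined at h_obs = 1")
    return 1.0 / (2.0 * (1.0 - h_obs))


def snap_to_count(h_printed: float, n: int) -> float:
    """Recover the exact heterozygote proportion k/n behind a printed,
    rounded observed heterozygosity.

    Published tables print Hobs to a few decimals, but the underlying
    quantity is a count over n individuals.  Statistics such as PI that
    divide by 1 - Hobs are sensitive to that rounding, so reproduction of
    published values uses round(h*n)/n rather than the printed decimal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return round(h_printed * n) / n


@dataclass
class ForensicReport:
    """Per-locus summaries plus the across-panel combinations."""

    summaries: list[LocusSummary]
    combined_pd: float
    combined_pe: float
    mean_pm: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "locus": s.locus, "h_obs": s.h_obs, "h_exp": s.h_exp,
                "pic": s.pic, "pm": s.pm, "pd": s.pd, "pe": s.pe,
                "pi": s.pi, "hwe_p": s.hwe_p,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows).set_index("locus")

    def to_csv(self, path: str | Path, decimals: int = 3) -> None:
        """Table-shaped CSV: full precision plus a rounded display copy."""
        df = self.to_dataframe()
        disp = df.round(decimals).add_suffix("_rounded")
        pd.concat([df, disp], axis=1).to_csv(path)


def combined_statistics(summaries: Sequence[LocusSummary]) -> ForensicReport:
    """Across-locus combinations: CPD = 1 - prod(1 - PD_l), CPE likewise,
    mean Pm arithmetic over loci."""
    if not summaries:
        raise ValueError("need at least one locus summary")
    pd_vals = np.array([s.pd for s in summaries])
    pe_vals = np.array([s.pe for s in summaries])
    pm_vals = np.array([s.pm for s in summaries])
    return ForensicReport(
        summaries=list(summaries),
        combined_pd=1.0 - float(np.prod(1.0 - pd_vals)),
        combined_pe=1.0 - float(np.prod(1.0 - pe_vals)),
        mean_pm=float(np.mean(pm_vals)),
    )


def summarize(g: GenotypeTable, hwe_method: str = "auto",
              hwe_reps: int = 100_000, seed: int = 1) -> ForensicReport:
    """Full forensic summary of a genotype table: one LocusSummary per
    locus (including an exact HWE p-value) plus combined statistics.
    Deterministic given the table and the HWE settings."""
    from .hwe import hwe_exact

    if not g.loci or not g.sample_ids:
        raise ValueError("empty genotype table")
    summaries = []
    for locus in g.loci:
        freqs, n = allele_frequencies(g, locus)
        h_obs = observed_heterozygosity(g, locus)
        pm = match_probability(g, locus)
        result = hwe_exact(g, locus, method=hwe_method, reps=hwe_reps, seed=seed)
        summaries.append(LocusSummary(
            locus=locus,
            h_obs=h_obs,
            h_exp=expected_heterozygosity(freqs, n),
            pic=pic(freqs),
            pm=pm,
            pd=power_of_discrimination(pm),
            pe=power_of_exclusion(h_obs),
            pi=paternity_index(h_obs) if h_obs < 1.0 else float("inf"),
            hwe_p=result.p_value,
        ))
    return combined_statistics(summaries)
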