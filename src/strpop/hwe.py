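"""Exact test of Hardy-Weinberg equilibrium at a multi-allelic locus.

The test conditions on the observed allele counts: given allele copy
counts m_1..m_k summing to 2n, the probability of a genotype array with
heterozygote counts {n_ij} is

    P = n! / prod_{i<=j} n_ij!  *  2^h  *  prod_i m_i! / (2n)!

with h the total number of heterozygous individuals.  The two-sided
"probability test" p-value sums P over every array at least as extreme
(P <= P_observed) — the convention of the classic exact-test software.

Arrays are enumerated exhaustively when the locus has few alleles and a
modest sample; otherwise the null is sampled by shuffling the 2n gene
copies and re-pairing them (Monte Carlo), with the +1/+1 estimator so the
reported p-value can never be zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .str_data import AlleleLabel, GenotypeTable

__all__ = ["HWEResult", "hwe_exact", "hwe_test_all", "bonferroni_alpha",
           "exact_test_counts", "genotype_counts"]

# exhaustive enumeration guards: beyond these, "auto" falls back to Monte
# Carlo.  The allele/sample cutover alone is not enough — with 4 alleles
# the array space grows combinatorially in n — so auto-dispatch also
# abandons an enumeration that exceeds a fixed array budget.
_ENUM_MAX_ALLELES = 4
_ENUM_MAX_N = 200
_ENUM_MAX_ARRAYS = 200_000

# tie tolerance when comparing log-probabilities (P <= P_obs including ties)
_LOG_TIE_EPS = 1e-9


@dataclass
class HWEResult:
    """Outcome of one locus's exact HWE test."""

    locus: str
    p_value: float
    method: str                      # "enumeration" | "monte_carlo"
    replicates: int | None = None
    seed: int | None = None
    alpha_corrected: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    @property
    def significant(self) -> bool | None:
        if self.alpha_corrected is None:
            return None
        return self.p_value < self.alpha_corrected


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test level alpha / n_tests (full precision;
    round only for display)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def genotype_counts(g: GenotypeTable, locus: str
                    ) -> tuple[list[AlleleLabel], dict[tuple[int, int], int]]:
    """Allele domain and genotype-class counts (i <= j index pairs)."""
    calls = g.genotypes_at(locus)
    if not calls:
        raise ValueError(f"no non-missing calls at locus {locus}")
    domain = sorted({a for call in calls for a in call})
    index = {a: i for i, a in enumerate(domain)}
    counts: dict[tuple[int, int], int] = {}
    for a, b in calls:
        i, j = index[a], index[b]
        key = (i, j) if i <= j else (j, i)
        counts[key] = counts.get(key, 0) + 1
    return domain, counts


def _allele_counts(k: int, genotypes: dict[tuple[int, int], int]) -> np.ndarray:
    m = np.zeros(k, dtype=np.int64)
    for (i, j), c in genotypes.items():
        m[i] += c
        m[j] += c
    return m


def _log_array_prob(n: int, m: np.ndarray, genotypes: dict[tuple[int, int], int]
                    ) -> float:
    two_n = 2 * n
    h = sum(c for (i, j), c in genotypes.items() if i != j)
    lp = (math.lgamma(n + 1) + h * math.log(2.0)
          + float(np.sum(gammaln(m + 1))) - math.lgamma(two_n + 1))
    lp -= sum(math.lgamma(c + 1) for c in genotypes.values())
    return lp


class _EnumerationBudgetExceeded(Exception):
    pass


def _enumerate_log_probs(m: np.ndarray, max_arrays: int | None = None
                         ) -> np.ndarray:
    """Log-probabilities of every genotype array compatible with allele
    counts *m*, by recursion over the heterozygote counts n_ij (i < j).
    Raises :class:`_EnumerationBudgetExceeded` past *max_arrays*."""
    k = len(m)
    n = int(m.sum()) // 2
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    const = (math.lgamma(n + 1) + float(np.sum(gammaln(m + 1)))
             - math.lgamma(2 * n + 1))
    out: list[float] = []
    het = np.zeros(k, dtype=np.int64)  # heterozygous copies used per allele

    def recurse(idx: int, log_fact_sum: float, h_total: int) -> None:
        if idx == len(pairs):
            diag = m - het
            if np.any(diag < 0) or np.any(diag % 2):
                return
            lf = log_fact_sum + sum(math.lgamma(d // 2 + 1) for d in diag)
            out.append(const + h_total * math.log(2.0) - lf)
            if max_arrays is not None and len(out) > max_arrays:
                raise _EnumerationBudgetExceeded
            return
        i, j = pairs[idx]
        # remaining heterozygous capacity bounds n_ij
        cap = min(m[i] - het[i], m[j] - het[j])
        for nij in range(int(cap) + 1):
            het[i] += nij
            het[j] += nij
            recurse(idx + 1, log_fact_sum + math.lgamma(nij + 1), h_total + nij)
            het[i] -= nij
            het[j] -= nij

    recurse(0, 0.0, 0)
    return np.asarray(out)


def exact_test_counts(genotypes: dict[tuple[int, int], int],
                      method: str = "auto", reps: int = 100_000,
                      seed: int = 1) -> tuple[float, str]:
    """Exact HWE p-value from genotype-class counts keyed by allele-index
    pairs (i <= j).  Returns (p_value, method_used)."""
    n = sum(genotypes.values())
    if n == 0:
        raise ValueError("no genotypes")
    k = 1 + max(max(key) for key in genotypes)
    m = _allele_counts(k, genotypes)
    observed = np.flatnonzero(m)
    if len(observed) <= 1:
        return 1.0, "enumeration"     # monomorphic: a single array is possible
    lp_obs = _log_array_prob(n, m, genotypes)
    if method == "auto":
        if len(observed) <= _ENUM_MAX_ALLELES and n <= _ENUM_MAX_N:
            try:
                # drop unobserved alleles; they contribute nothing
                lps = _enumerate_log_probs(m[observed],
                                           max_arrays=_ENUM_MAX_ARRAYS)
            except _EnumerationBudgetExceeded:
                pass
            else:
                p = float(np.sum(np.exp(lps[lps <= lp_obs + _LOG_TIE_EPS])))
                return min(p, 1.0), "enumeration"
        method = "mc"
    if method in ("enumerate", "enumeration"):
        lps = _enumerate_log_probs(m[observed])
        p = float(np.sum(np.exp(lps[lps <= lp_obs + _LOG_TIE_EPS])))
        return min(p, 1.0), "enumeration"
    if method in ("mc", "monte_carlo"):
        p = _monte_carlo_p(n, m, lp_obs, reps=reps, seed=seed)
        return p, "monte_carlo"
    raise ValueError(f"unknown method {method!r}")


def _monte_carlo_p(n: int, m: np.ndarray, lp_obs: float, reps: int, seed: int,
                   chunk: int = 20_000) -> float:
    """Shuffle the 2n gene copies, re-pair consecutive copies, and count
    replicates whose array probability is <= the observed one."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(m)
    copies = np.repeat(np.arange(k), m)
    const = (math.lgamma(n + 1) + float(np.sum(gammaln(m + 1)))
             - math.lgamma(2 * n + 1))
    log2 = math.log(2.0)
    hits = 0
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        perm = rng.permuted(np.tile(copies, (r, 1)), axis=1)
        a = perm[:, 0::2]
        b = perm[:, 1::2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        h = (lo != hi).sum(axis=1)
        codes = lo * k + hi + (np.arange(r)[:, None] * k * k)
        counts = np.bincount(codes.ravel(), minlength=r * k * k).reshape(r, k * k)
        lfact = gammaln(counts + 1.0).sum(axis=1)
        lps = const + h * log2 - lfact
        hits += int(np.sum(lps <= lp_obs + _LOG_TIE_EPS))
        done += r
    return (1 + hits) / (1 + reps)


def hwe_exact(g: GenotypeTable, locus: str, method: str = "auto",
              reps: int = 100_000, seed: int = 1,
              alpha_corrected: float | None = None) -> HWEResult:
    """Exact HWE test at one locus of a genotype table."""
    _, genotypes = genotype_counts(g, locus)
    p, used = exact_test_counts(genotypes, method=method, reps=reps, seed=seed)
    mc = used == "monte_carlo"
    return HWEResult(locus=locus, p_value=p, method=used,
                     replicates=reps if mc else None,
                     seed=seed if mc else None,
                     alpha_corrected=alpha_corrected)


def hwe_test_all(g: GenotypeTable, alpha: float = 0.05, method: str = "auto",
                 reps: int = 100_000, seed: int = 1) -> list[HWEResult]:
    """Test every locus, flagging significance at the Bonferroni-corrected
    level alpha / (number of loci)."""
    corrected = bonferroni_alpha(alpha, len(g.loci))
    return [hwe_exact(g, locus, method=method, reps=reps, seed=seed,
                      alpha_corrected=corrected) for locus in g.loci]
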