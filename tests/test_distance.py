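"""Nei DA distance and Weir-Cockerham theta, with an independent
variance-component oracle and simulation-based recovery checks."""

import numpy as np
import pytest

import strpop as sp
from strpop.distance import _theta_components, fst_permutation_p
from strpop.str_data import AlleleLabel, AlleleFrequencyTable, PopulationSet

A = AlleleLabel.parse


def popset(freqs_by_pop: dict[str, dict[str, dict[str, float]]],
           n: int = 100) -> PopulationSet:
    pops = {}
    for name, by_locus in freqs_by_pop.items():
        loci = list(by_locus)
        pops[name] = AlleleFrequencyTable(
            loci, {locus: n for locus in loci},
            {locus: {A(a): f for a, f in fr.items()}
             for locus, fr in by_locus.items()})
    return PopulationSet(pops)


class TestNeiDA:
    def test_identical_populations_zero(self):
        ps = popset({"x": {"L": {"8": 0.5, "9": 0.5}},
                     "y": {"L": {"8": 0.5, "9": 0.5}}})
        assert sp.nei_da(ps, "x", "y") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_one(self):
        ps = popset({"x": {"L": {"8": 1.0}}, "y": {"L": {"9": 1.0}}})
        assert sp.nei_da(ps, "x", "y") == pytest.approx(1.0)

    def test_closed_form_half_overlap(self):
        ps = popset({"x": {"L": {"8": 1.0}}, "y": {"L": {"8": 0.5, "9": 0.5}}})
        assert sp.nei_da(ps, "x", "y") == pytest.approx(1 - np.sqrt(0.5))

    def test_symmetric_and_relabel_invariant(self):
        ps = popset({"x": {"L": {"8": 0.7, "9": 0.3}},
                     "y": {"L": {"8": 0.2, "9": 0.8}}})
        d = sp.nei_da(ps, "x", "y")
        assert d == pytest.approx(sp.nei_da(ps, "y", "x"))
        relabeled = popset({"x": {"L": {"12": 0.7, "13": 0.3}},
                            "y": {"L": {"12": 0.2, "13": 0.8}}})
        assert sp.nei_da(relabeled, "x", "y") == pytest.approx(d)

    def test_identical_extra_locus_rescales(self):
        one = popset({"x": {"L1": {"8": 1.0}},
                      "y": {"L1": {"8": 0.5, "9": 0.5}}})
        two = popset({"x": {"L1": {"8": 1.0}, "L2": {"10": 0.5, "11": 0.5}},
                      "y": {"L1": {"8": 0.5, "9": 0.5}, "L2": {"10": 0.5, "11": 0.5}}})
        d1 = sp.nei_da(one, "x", "y")
        assert sp.nei_da(two, "x", "y") == pytest.approx(d1 * 1 / 2)

    def test_matrix_invariants(self):
        cfg = sp.SimulationConfig(loci=("L1", "L2", "L3"), alleles_per_locus=4,
                                  n=50, f_st=0.1, n_pops=4, seed=2)
        ps, _ = sp.sample_balding_nichols(cfg)
        dm = sp.da_matrix(ps)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        assert np.all(dm.data >= 0) and np.all(dm.data <= 1)
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j:
                    assert dm.data[i, j] == pytest.approx(sp.nei_da(ps, a, b))


def _theta_oracle(c1, c2):
    """Term-by-term Weir-Cockerham components for one locus, two
    populations, HWE-expected heterozygosity; plain-Python re-derivation."""
    c1, c2 = list(map(float, c1)), list(map(float, c2))
    n1, n2 = sum(c1) / 2, sum(c2) / 2
    nbar = (n1 + n2) / 2
    nc = 2 * nbar - (n1 ** 2 + n2 ** 2) / (2 * nbar)
    a_sum = abc_sum = 0.0
    for k in range(len(c1)):
        p1, p2 = c1[k] / (2 * n1), c2[k] / (2 * n2)
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / (2 * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


class TestWeirCockerham:
    def test_identical_counts_near_zero(self):
        ps = popset({"x": {"L": {"8": 0.6, "9": 0.4}},
                     "y": {"L": {"8": 0.6, "9": 0.4}}}, n=100)
        assert abs(sp.wc_fst(ps, "x", "y").theta) <= 0.01

    def test_fixed_difference_is_one(self):
        ps = popset({"x": {"L": {"8": 1.0}}, "y": {"L": {"9": 1.0}}}, n=50)
        assert sp.wc_fst(ps, "x", "y").theta == pytest.approx(1.0)

    @pytest.mark.parametrize("c1,c2", [
        ([30, 70], [60, 40]),
        ([10, 20, 70], [40, 40, 20]),
        ([99, 1], [90, 10]),
    ])
    def test_components_match_oracle(self, c1, c2):
        sa, sabc = _theta_components(np.array(c1, float), np.array(c2, float))
        oa, oabc = _theta_oracle(c1, c2)
        assert sa == pytest.approx(oa)
        assert sabc == pytest.approx(oabc)

    def test_multilocus_is_ratio_of_sums(self):
        ps = popset({"x": {"L1": {"8": 0.9, "9": 0.1}, "L2": {"8": 0.5, "9": 0.5}},
                     "y": {"L1": {"8": 0.3, "9": 0.7}, "L2": {"8": 0.5, "9": 0.5}}})
        res = sp.wc_fst(ps, "x", "y")
        num = den = 0.0
        for locus in ("L1", "L2"):
            c1 = [ps.populations["x"].counts(locus).get(A(a), 0) for a in ("8", "9")]
            c2 = [ps.populations["y"].counts(locus).get(A(a), 0) for a in ("8", "9")]
            oa, oabc = _theta_oracle(c1, c2)
            num += oa
            den += oabc
        assert res.theta == pytest.approx(num / den)

    def test_balding_nichols_recovery(self):
        """Mean multi-locus theta over replicates lands within 30% of the
        generating F (20 loci, 5 alleles, 200 per population)."""
        for f in (0.05, 0.1, 0.2):
            thetas = []
            for s in range(6):
                cfg = sp.SimulationConfig(
                    loci=tuple(f"L{i}" for i in range(20)), alleles_per_locus=5,
                    n=200, f_st=f, n_pops=2, seed=300 + s)
                ps, _ = sp.sample_balding_nichols(cfg)
                thetas.append(sp.wc_fst(ps, "pop1", "pop2").theta)
            assert abs(np.mean(thetas) - f) / f < 0.3

    def test_da_increases_with_f(self):
        from scipy.stats import spearmanr
        grid = [0.01, 0.05, 0.1, 0.2]
        das = []
        for f in grid:
            vals = []
            for s in range(4):
                cfg = sp.SimulationConfig(
                    loci=tuple(f"L{i}" for i in range(20)), alleles_per_locus=5,
                    n=200, f_st=f, n_pops=2, seed=600 + s)
                ps, _ = sp.sample_balding_nichols(cfg)
                vals.append(sp.nei_da(ps, "pop1", "pop2"))
            das.append(np.mean(vals))
        rho, _ = spearmanr(grid, das)
        assert rho > 0.9
        assert das == sorted(das)


class TestPermutationTest:
    def test_identical_populations_p_near_one(self):
        ps = popset({"x": {"L": {"8": 0.5, "9": 0.5}},
                     "y": {"L": {"8": 0.5, "9": 0.5}}}, n=50)
        p = fst_permutation_p(ps, "x", "y", reps=500, seed=1)["L"]
        assert p > 0.5

    def test_fixed_difference_minimal_p(self):
        ps = popset({"x": {"L": {"8": 1.0}}, "y": {"L": {"9": 1.0}}}, n=50)
        reps = 400
        p = fst_permutation_p(ps, "x", "y", reps=reps, seed=1)["L"]
        assert p == pytest.approx(1 / (reps + 1))

    def test_reproducible_given_seed(self):
        ps = popset({"x": {"L": {"8": 0.7, "9": 0.3}},
                     "y": {"L": {"8": 0.4, "9": 0.6}}}, n=60)
        p1 = fst_permutation_p(ps, "x", "y", reps=1_000, seed=4)
        p2 = fst_permutation_p(ps, "x", "y", reps=1_000, seed=4)
        assert p1 == p2

    def test_power_under_drift(self):
        """Differentiated pair (F = 0.1, n = 100): most loci significant
        at the corrected 0.003 level."""
        cfg = sp.SimulationConfig(loci=tuple(f"L{i}" for i in range(20)),
                                  alleles_per_locus=5, n=100, f_st=0.1,
                                  n_pops=2, seed=77)
        ps, _ = sp.sample_balding_nichols(cfg)
        pvals = fst_permutation_p(ps, "pop1", "pop2", reps=2_000, seed=1)
        assert np.median(list(pvals.values())) < 0.003

    def test_zero_reps_rejected(self):
        ps = popset({"x": {"L": {"8": 1.0}}, "y": {"L": {"9": 1.0}}})
        with pytest.raises(ValueError):
            fst_permutation_p(ps, "x", "y", reps=0)
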