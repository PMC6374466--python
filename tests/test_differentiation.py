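"""Weir-Cockerham theta, Jost's D, exact tests and the Holm correction,
each checked against an independent oracle on small instances."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from conftest import make_table
from coralconnect.popgen import (
    exact_differentiation_test, exact_locus_test, global_fst, jost_dest,
    jost_dest_value, pairwise_fst, sequential_bonferroni, wc_theta,
)
from coralconnect.synthetic import SimGenotypeConfig, generate_genotypes


def brute_force_theta(pop_genotypes: dict[str, list[tuple[int, int]]]) -> float:
    """Independent single-locus Weir-Cockerham theta, written directly from
    the variance-component definitions with plain loops."""
    pops = list(pop_genotypes)
    r = len(pops)
    alleles = sorted({a for g in pop_genotypes.values() for pair in g for a in pair})
    n = {p: len(pop_genotypes[p]) for p in pops}
    nbar = sum(n.values()) / r
    nc = (r * nbar - sum(v * v for v in n.values()) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for allele in alleles:
        p_hat, h_hat = {}, {}
        for p in pops:
            copies = sum(pair.count(allele) for pair in pop_genotypes[p])
            p_hat[p] = copies / (2 * n[p])
            h_hat[p] = sum(
                1 for pair in pop_genotypes[p]
                if pair[0] != pair[1] and allele in pair
            ) / n[p]
        pbar = sum(n[p] * p_hat[p] for p in pops) / (r * nbar)
        s2 = sum(n[p] * (p_hat[p] - pbar) ** 2 for p in pops) / ((r - 1) * nbar)
        hbar = sum(n[p] * h_hat[p] for p in pops) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWCTheta:
    def test_null_two_large_identical_pools(self):
        t = generate_genotypes(SimGenotypeConfig(
            n_pops=2, n_per_pop=500, n_loci=4, fst_target=0.0, seed=9))
        assert abs(wc_theta(t)) < 0.01

    def test_fixed_alternative_alleles_give_one(self):
        t = make_table({
            "A": [[(1, 1)]] * 6,
            "B": [[(2, 2)]] * 6,
        })
        assert wc_theta(t) == pytest.approx(1.0)

    def test_matches_independent_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            geno = {
                "A": [tuple(sorted(rng.integers(1, 5, 2))) for _ in range(10)],
                "B": [tuple(sorted(rng.integers(1, 6, 2))) for _ in range(8)],
            }
            t = make_table({p: [[g] for g in geno[p]] for p in geno})
            assert wc_theta(t) == pytest.approx(brute_force_theta(geno),
                                                abs=1e-12)

    def test_multilocus_sums_components_not_averages(self):
        rng = np.random.default_rng(3)
        geno1 = {p: [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(9)]
                 for p in "AB"}
        geno2 = {p: [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(9)]
                 for p in "AB"}
        t = make_table({
            p: [[geno1[p][i], geno2[p][i]] for i in range(9)] for p in "AB"
        })
        t1 = brute_force_theta(geno1)
        t2 = brute_force_theta(geno2)
        multi = wc_theta(t)
        lo, hi = min(t1, t2), max(t1, t2)
        assert lo - 1e-9 <= multi <= hi + 1e-9

    def test_pairwise_matrix_and_bounds(self):
        t = generate_genotypes(SimGenotypeConfig(
            n_pops=4, n_per_pop=15, fst_target=0.10, seed=12))
        fst, pmat = pairwise_fst(t, n_perm=99, seed=0)
        assert ((fst.values >= -0.05) & (fst.values <= 1.0)).all()
        off = ~np.eye(4, dtype=bool)
        assert ((pmat.values[off] > 0) & (pmat.values[off] <= 1)).all()

    def test_empty_calls_population_rejected(self):
        t = make_table({"A": [[(0, 0)]], "B": [[(1, 2)]]})
        with pytest.raises(ValueError, match="A"):
            wc_theta(t)


class TestJostD:
    def test_identical_pools_near_zero(self):
        t = generate_genotypes(SimGenotypeConfig(
            n_pops=2, n_per_pop=400, n_loci=4, fst_target=0.0, seed=30))
        assert abs(jost_dest_value(t, t.pop_names)) < 0.02

    def test_fixed_alternative_alleles_give_one(self):
        t = make_table({"A": [[(1, 1)]] * 5, "B": [[(2, 2)]] * 5})
        assert jost_dest_value(t, ["A", "B"]) == pytest.approx(1.0)

    def test_matches_hand_computed_formula(self):
        # pop A: genotypes (1,1),(1,2),(2,2); pop B: (1,2),(2,2),(2,2)
        t = make_table({
            "A": [[(1, 1)], [(1, 2)], [(2, 2)]],
            "B": [[(1, 2)], [(2, 2)], [(2, 2)]],
        })
        # hand evaluation of the Nei-Chesser corrected formula, k=2, n=3:
        pA, pB = 0.5, 1.0 / 6.0              # frequency of allele 1
        ho = (1.0 / 3.0 + 1.0 / 3.0) / 2.0
        hs_raw = 1.0 - ((pA**2 + (1 - pA)**2) + (pB**2 + (1 - pB)**2)) / 2.0
        pbar = (pA + pB) / 2.0
        ht_raw = 1.0 - (pbar**2 + (1 - pbar)**2)
        n_h = 3.0
        hs = (n_h / (n_h - 1)) * (hs_raw - ho / (2 * n_h))
        ht = ht_raw + hs / (2 * n_h) - ho / (4 * n_h)
        expected = 2.0 * (ht - hs) / (1.0 - hs)
        assert jost_dest_value(t, ["A", "B"]) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_pairwise_matrix_symmetric(self):
        t = generate_genotypes(SimGenotypeConfig(
            n_pops=3, n_per_pop=12, fst_target=0.1, seed=31))
        m = jost_dest(t)
        assert np.allclose(m.values, m.values.T)


class TestExactTest:
    def test_identical_tables_p_near_one(self):
        tab = np.array([[10, 10], [10, 10]])
        assert exact_locus_test(tab, 2000, seed=0) >= 0.5

    def test_complete_separation(self):
        tab = np.array([[10, 0], [0, 10]])
        assert exact_locus_test(tab, 5000, seed=0) <= 0.001

    def test_matches_fisher_exact_within_mc_error(self):
        tab = np.array([[8, 2], [3, 9]])
        n = 20_000
        p_mc = exact_locus_test(tab, n, seed=1)
        p_true = fisher_exact(tab)[1]
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_mc - p_true) < 3 * se

    def test_monomorphic_locus_skipped_and_combined(self):
        t = make_table({
            "A": [[(1, 1), (7, 7)], [(1, 2), (7, 7)], [(2, 2), (7, 7)]],
            "B": [[(2, 2), (7, 7)], [(2, 2), (7, 7)], [(1, 2), (7, 7)]],
        })
        res = exact_differentiation_test(t, ("A", "B"), 500, seed=2)
        assert res.skipped == ["L02"]
        assert set(res.per_locus) == {"L01"}
        assert 0 < res.combined_p <= 1


class TestHolm:
    def test_hand_evaluated_example(self):
        flags = sequential_bonferroni([0.01, 0.02, 0.04], alpha=0.05)
        # 0.01 < 0.05/3, 0.02 < 0.05/2, 0.04 < 0.05
        assert flags.tolist() == [True, True, True]

    def test_stops_at_first_failure(self):
        flags = sequential_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
        # 0.03 >= 0.025 stops the procedure; 0.04 would pass alone but must not
        assert flags.tolist() == [True, False, False]

    def test_trivial_cases(self):
        assert not sequential_bonferroni([1.0, 1.0, 1.0]).any()
        assert sequential_bonferroni([0.049], alpha=0.05).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_p(self, pvals):
        flags = sequential_bonferroni(pvals, alpha=0.05)
        p = np.asarray(pvals)
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] <= p[j] and flags[j]:
                    assert flags[i]

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = sequential_bonferroni(pvals, alpha=0.05)
        theirs = multipletests(pvals, alpha=0.05, method="holm")[0]
        # statsmodels uses <= where the step-down rule here uses <; they can
        # differ only when a p-value sits exactly on a boundary
        boundary = any(
            np.isclose(sorted(pvals)[k], 0.05 / (len(pvals) - k))
            for k in range(len(pvals))
        )
        if not boundary:
            assert ours.tolist() == theirs.tolist()
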