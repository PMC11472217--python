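"""Rank-test suite: Friedman, Skillings-Mack, permutation agreement, Holm post hocs."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from laminarhrf.groupstats import (
    _friedman_statistic,
    _skillings_mack_statistic,
    friedman,
    posthoc_pairwise,
    skillings_mack,
)


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        table = np.tile(np.arange(4.0)[:, None], (1, 3))
        res = friedman(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0, abs=0.01)

    def test_perfect_ordering_matches_exhaustive_permutation_oracle(self):
        # 3 blocks x 3 treatments, strictly ordered rows. Oracle: enumerate
        # all 6^3 within-block orderings of the rank patterns.
        table = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [1.5, 2.5, 3.5]])
        stat = _friedman_statistic(table)
        dist = []
        perms = list(itertools.permutations([1.0, 2.0, 3.0]))
        for r1 in perms:
            for r2 in perms:
                for r3 in perms:
                    dist.append(_friedman_statistic(np.array([r1, r2, r3])))
        dist = np.array(dist)
        assert stat == pytest.approx(dist.max()) == pytest.approx(6.0)
        p_exact = np.mean(dist >= stat - 1e-12)
        res = friedman(table, n_permutations=4000, seed=0)
        assert res.pvalue == pytest.approx(p_exact, abs=0.01)

    def test_statistic_matches_scipy_on_tie_free_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.standard_normal((10, 4))
            ours = friedman(table, force_asymptotic=True)
            ref = sps.friedmanchisquare(*table.T)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_asymptotic_close_to_permutation_for_large_blocks(self):
        # mild planted treatment effects keep p in the decision-relevant range
        rng = np.random.default_rng(1)
        for _ in range(5):
            table = rng.standard_normal((10, 4)) + np.array([0.0, 0.3, 0.6, 0.9])
            asym = friedman(table, force_asymptotic=True).pvalue
            stat = _friedman_statistic(table)
            count = 0
            n_perm = 3000
            prng = np.random.default_rng(2)
            for _ in range(n_perm):
                perm = np.vstack([prng.permutation(row) for row in table])
                if _friedman_statistic(perm) >= stat - 1e-12:
                    count += 1
            p_perm = (count + 1) / (n_perm + 1)
            assert abs(asym - p_perm) < 0.03

    def test_missing_cells_redirected(self):
        table = np.array([[1.0, 2.0, np.nan], [3.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="skillings_mack"):
            friedman(table)


class TestSkillingsMack:
    def test_reduces_to_friedman_on_complete_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            table = rng.standard_normal((8, 4))  # continuous, tie-free
            f = friedman(table, force_asymptotic=True)
            sm = skillings_mack(table, force_asymptotic=True)
            assert sm.statistic == pytest.approx(f.statistic, abs=1e-10)

    def test_identical_treatments_with_missing_cells(self):
        table = np.tile(np.arange(5.0)[:, None], (1, 4))
        table[0, 2] = np.nan
        table[3, 0] = np.nan
        res = skillings_mack(table, force_asymptotic=True)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_asymptotic_close_to_permutation_with_missing_cells(self):
        rng = np.random.default_rng(4)
        table = rng.standard_normal((10, 4))
        mask = rng.random((10, 4)) < 0.2
        mask[:, 0] &= mask.sum(axis=1) < 3  # keep blocks usable
        table[mask] = np.nan
        asym = skillings_mack(table, force_asymptotic=True).pvalue
        obs = np.isfinite(table)
        stat, _ = _skillings_mack_statistic(table)
        prng = np.random.default_rng(5)
        n_perm = 2000
        count = 0
        for _ in range(n_perm):
            perm = table.copy()
            for i in range(table.shape[0]):
                cols = np.where(obs[i])[0]
                perm[i, cols] = table[i, cols][prng.permutation(len(cols))]
            if _skillings_mack_statistic(perm)[0] >= stat - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        band = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm) + 0.02
        assert abs(asym - p_perm) < band

    def test_unobserved_treatment_rejected(self):
        table = np.ones((4, 3))
        table[:, 2] = np.nan
        with pytest.raises(ValueError, match="observed"):
            skillings_mack(table)

    def test_detects_planted_amplitude_difference_at_high_power(self):
        # GE-vs-SE-sized effect (2.17 vs 0.90, dispersions 0.9/0.5, n = 9):
        # Wilcoxon-style paired comparison should detect nearly always
        # a Monte-Carlo oracle run put the signed-rank power for this effect
        # size at n = 9 near 0.86
        rng = np.random.default_rng(6)
        n_sims, hits = 200, 0
        for _ in range(n_sims):
            ge = rng.normal(2.17, 0.9, 9)
            se = rng.normal(0.90, 0.5, 9)
            hits += sps.wilcoxon(ge - se).pvalue < 0.05
        assert hits / n_sims > 0.78


class TestPosthoc:
    def test_single_comparison_unadjusted(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(1.0, 1.0, 12), rng.normal(0.0, 1.0, 12)
        out = posthoc_pairwise([("only", x, y)])
        assert out["p_adjusted"][0] == pytest.approx(out["p"][0])

    def test_holm_arithmetic_identical_pvalues(self):
        # m comparisons sharing one p: smallest adjusted = m * p (capped at 1)
        rng = np.random.default_rng(8)
        x = rng.normal(0.8, 1.0, 10)
        y = rng.normal(0.0, 1.0, 10)
        fam = [(f"c{i}", x, y) for i in range(3)]
        out = posthoc_pairwise(fam)
        p0 = out["p"][0]
        assert out["p_adjusted"].min() == pytest.approx(min(3 * p0, 1.0))

    def test_holm_matches_brute_force_step_down(self):
        # independent enumeration of the step-down rule on the realized p's
        rng = np.random.default_rng(9)
        fam = [
            (f"c{i}", rng.normal(0.5 * i, 1.0, 15), rng.normal(0.0, 1.0, 15))
            for i in range(4)
        ]
        out = posthoc_pairwise(fam)
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        assert np.allclose(out["p_adjusted"].to_numpy(), adj, atol=1e-12)

    def test_holm_dominates_bonferroni(self):
        rng = np.random.default_rng(10)
        fam = [
            (f"c{i}", rng.normal(0.3 * i, 1.0, 12), rng.normal(0.0, 1.0, 12))
            for i in range(5)
        ]
        out = posthoc_pairwise(fam)
        bonf = np.minimum(out["p"].to_numpy() * len(fam), 1.0)
        assert np.all(out["p_adjusted"].to_numpy() <= bonf + 1e-12)

    def test_underpowered_comparisons_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 1.5])
        out = posthoc_pairwise([("tiny", x, y)])
        assert bool(out["underpowered"][0])

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            posthoc_pairwise([])
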