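import itertools

import numpy as np
import pytest
from scipy import stats

from cyclederg import (
    DataValidationError,
    DeregulationResult,
    GeneSet,
    PanCancerSimConfig,
    gene_medians,
    matched_paired_test,
    pancancer_rank,
    permutation_null,
    quantile_reference,
    ranksum_test,
    set_fold_change,
    simulate_pancancer,
)
from cyclederg.geneset_deregulation import exhaustive_permutation_p


class TestGeneMedians:
    def test_matches_brute_force_sort_and_pick(self):
        rng = np.random.default_rng(0)
        from cyclederg import ExpressionDataset

        vals = rng.normal(size=(50, 20))
        ds = ExpressionDataset(
            [f"g{i}" for i in range(50)], [f"s{j}" for j in range(20)], vals
        )
        med = gene_medians(ds, "default")
        for i, g in enumerate(ds.gene_ids):
            row = np.sort(vals[i])
            naive = (row[9] + row[10]) / 2  # even n: mean of middle pair
            assert med[g] == pytest.approx(naive)

    def test_na_handling_and_unknown_cohort(self, tiny_dataset):
        med = gene_medians(tiny_dataset, "B")
        assert med["ACTB"] == 6.0  # NA dropped from the pair
        with pytest.raises(DataValidationError):
            gene_medians(tiny_dataset, "nope")

    def test_outlier_robustness(self, tiny_dataset):
        # CDK4 in cohort B is (10, 10); in A it is (1, 2) -> median 1.5
        med = gene_medians(tiny_dataset, "A")
        assert med["CDK4"] == 1.5


class TestSetFoldChange:
    def test_direct_arithmetic(self):
        medians = {"a": 3.0, "b": 4.0, "c": 1.0, "d": 2.0}
        gs = GeneSet("S", "", frozenset({"a", "b"}))
        ms, mo, fc = set_fold_change(medians, gs)
        assert (ms, mo, fc) == (3.5, 1.5, 2.0)

    def test_null_set_gives_zero(self):
        # set members take exactly the background's value multiset
        medians = {f"g{i}": float(i % 10) for i in range(100)}
        gs = GeneSet("S", "", frozenset(f"g{i}" for i in range(10)))
        _, _, fc = set_fold_change(medians, gs)
        assert fc == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        medians = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=100))}
        gs = GeneSet("S", "", frozenset(f"g{i}" for i in range(30)))
        _, _, fc = set_fold_change(medians, gs)
        shifted = {k: v + 7.3 for k, v in medians.items()}
        _, _, fc2 = set_fold_change(shifted, gs)
        assert fc2 == pytest.approx(fc)

    def test_empty_intersection_names_the_set(self):
        gs = GeneSet("CC", "", frozenset({"nope"}))
        with pytest.raises(DataValidationError, match="CC"):
            set_fold_change({"a": 1.0, "b": 2.0}, gs)

    def test_recovers_injected_delta(self, small_sim):
        ds, truth, gset = small_sim
        med = gene_medians(ds, "C00")
        _, _, fc = set_fold_change(med, gset)
        assert fc == pytest.approx(truth["C00"], abs=0.3)


class TestRanksum:
    def test_symmetry_gives_p_one(self):
        assert ranksum_test([1, 2], [1, 2]) == pytest.approx(1.0)

    def test_exact_small_sample(self):
        # all C(6,3)=20 rank splits; {1,2,3} vs {4,5,6} is the extreme, 2/20
        assert ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_tied_returns_one(self):
        assert ranksum_test([2, 2, 2], [2, 2]) == 1.0

    def test_matches_monte_carlo_permutation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.8, 1.0, 30)
        p = ranksum_test(x, y)
        # Monte-Carlo permutation of the rank-sum statistic
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:30].sum()
        mu = ranks.sum() * 30 / 60
        draws = 20_000
        count = 0
        for _ in range(draws):
            perm = rng.permutation(60)
            w = ranks[perm[:30]].sum()
            if abs(w - mu) >= abs(obs - mu) - 1e-9:
                count += 1
        p_mc = count / draws
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-9) / draws)
        assert abs(p - p_mc) <= 3 * se + 1e-4


class TestPermutationNull:
    def test_all_equal_medians_give_p_one(self):
        null = permutation_null(np.ones(10), 3, observed=0.0, M=50, seed=1)
        assert np.all(null.null_values == 0.0)
        assert null.p_emp == 1.0  # ties count as >=

    def test_extreme_observed_hits_floor(self):
        rng = np.random.default_rng(3)
        null = permutation_null(rng.normal(size=20), 5, observed=100.0, M=99, seed=2)
        assert null.p_emp == pytest.approx(1 / 100)

    def test_exhaustive_four_gene_case(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        p_ex = exhaustive_permutation_p(values, 2, observed=2.0)
        assert p_ex == pytest.approx(1 / 6)

    def test_monte_carlo_converges_to_exhaustive(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        null = permutation_null(values, 2, observed=2.0, M=20_000, seed=4)
        assert null.p_emp == pytest.approx(1 / 6, abs=0.01)

    @pytest.mark.parametrize("n,k", [(5, 2), (6, 3), (8, 3)])
    def test_monte_carlo_matches_exhaustive_small_instances(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        values = rng.normal(size=n)
        obs = float(np.median(values[:k]) - np.median(values[k:]))
        p_ex = exhaustive_permutation_p(values, k, obs)
        M = 10_000
        null = permutation_null(values, k, obs, M=M, seed=5)
        se = np.sqrt(p_ex * (1 - p_ex) / M)
        assert abs(null.p_emp - p_ex) <= 3 * se + 1 / M

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=30)
        a = permutation_null(vals, 10, 0.1, M=500, seed=7)
        b = permutation_null(vals, 10, 0.1, M=500, seed=7)
        np.testing.assert_array_equal(a.null_values, b.null_values)

    def test_null_calibration_rejection_rate(self):
        """Under delta=0 the permutation p rejects at about the nominal rate."""
        n_sims = 200
        alpha = 0.05
        rejections = 0
        rng = np.random.default_rng(8)
        for _ in range(n_sims):
            medians = rng.normal(size=150)
            k = 25
            obs = float(np.median(medians[:k]) - np.median(medians[k:]))
            null = permutation_null(
                medians, k, obs, M=400, seed=int(rng.integers(2**31 - 1))
            )
            if null.p_emp <= alpha:
                rejections += 1
        lo, hi = stats.binom.interval(0.95, n_sims, alpha)
        assert lo <= rejections <= hi


class TestPancancerRank:
    def _mk(self, cohort, fc, p=0.5):
        return DeregulationResult(cohort, 10, 90, fc, 0.0, fc, p)

    def test_orders_by_fold_change(self):
        ranked = pancancer_rank([self._mk("A", 1.0), self._mk("B", 0.5), self._mk("C", 1.5)])
        assert [r.cohort for r in ranked] == ["C", "A", "B"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_broken_by_smaller_p_then_label(self):
        ranked = pancancer_rank([self._mk("A", 1.0, 0.2), self._mk("B", 1.0, 0.01)])
        assert [r.cohort for r in ranked] == ["B", "A"]
        ranked = pancancer_rank([self._mk("B", 1.0, 0.2), self._mk("A", 1.0, 0.2)])
        assert [r.cohort for r in ranked] == ["A", "B"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DataValidationError):
            pancancer_rank([self._mk("A", 1.0), self._mk("A", 0.5)])

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(9)
        results = [self._mk(f"C{i}", float(rng.normal())) for i in range(24)]
        ranked = pancancer_rank(results)
        assert sorted(r.rank for r in ranked) == list(range(1, 25))

    def test_recovers_delta_order_on_simulation(self):
        deltas = np.linspace(0.2, 2.0, 6)
        cfg = PanCancerSimConfig(
            n_cohorts=6, genes_per_matrix=500, samples_per_cohort=40,
            set_size=50, delta=deltas, seed=10,
        )
        ds, truth, gset = simulate_pancancer(cfg)
        results = []
        for cohort in ds.cohorts():
            med = gene_medians(ds, cohort)
            ms, mo, fc = set_fold_change(med, gset)
            p = ranksum_test(
                [v for g, v in med.items() if g in gset.members],
                [v for g, v in med.items() if g not in gset.members],
            )
            results.append(DeregulationResult(cohort, 50, 450, ms, mo, fc, p))
        ranked = pancancer_rank(results)
        # largest injected delta should rank first, smallest last
        assert ranked[0].cohort == "C05"
        assert ranked[-1].cohort == "C00"


class TestQuantileReference:
    def test_linear_interpolation_on_one_to_five(self):
        q = quantile_reference(np.arange(1.0, 6.0))
        assert (q.q25, q.q50, q.q75) == (2.0, 3.0, 4.0)

    def test_all_equal(self):
        q = quantile_reference(np.full(10, 3.3))
        assert q.q25 == q.q50 == q.q75 == 3.3

    def test_uniform_draws_close_to_theoretical(self):
        rng = np.random.default_rng(11)
        q = quantile_reference(rng.uniform(0, 1, 10_000))
        assert q.q25 == pytest.approx(0.25, abs=0.02)
        assert q.q50 == pytest.approx(0.50, abs=0.02)
        assert q.q75 == pytest.approx(0.75, abs=0.02)

    def test_too_few_values(self):
        with pytest.raises(DataValidationError):
            quantile_reference([1.0, 2.0, 3.0])


class TestMatchedPaired:
    def test_constant_shift_gives_exact_minimum_p(self):
        normal = np.arange(10, dtype=float)
        tumor = normal + 1.0
        p, direction = matched_paired_test(tumor, normal)
        assert direction == 1
        # all 2^10 sign assignments; only the all-positive one is as extreme
        # on each side -> two-sided p = 2/1024
        assert p == pytest.approx(2 / 1024)

    def test_identical_pairs(self):
        x = np.arange(8, dtype=float)
        p, direction = matched_paired_test(x, x)
        assert p == 1.0 and direction == 0

    def test_flip_symmetry(self):
        rng = np.random.default_rng(12)
        normal = rng.normal(size=9)
        tumor = normal + rng.normal(0.4, 1.0, size=9)
        p1, _ = matched_paired_test(tumor, normal)
        p2, _ = matched_paired_test(normal, tumor)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_in_untied_regime(self):
        rng = np.random.default_rng(13)
        normal = rng.normal(size=11)
        tumor = normal + rng.normal(0.5, 1.0, size=11)
        p, _ = matched_paired_test(tumor, normal)
        ref = stats.wilcoxon(tumor, normal, alternative="two-sided",
                             method="exact").pvalue
        assert p == pytest.approx(ref)
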