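import itertools

import numpy as np
import pandas as pd
import pytest

from slscreen import mutex as mx


def brute_force_lower_tail(q, k):
    """P(C <= k) by summing over all 2^n Bernoulli outcome vectors."""
    n = len(q)
    total = 0.0
    for bits in itertools.product([0, 1], repeat=n):
        prob = 1.0
        for b, qi in zip(bits, q):
            prob *= qi if b else 1 - qi
        if sum(bits) <= k:
            total += prob
    return total


class TestBackground:
    def test_homogeneous_matrix_recovers_frequency(self):
        rng = np.random.default_rng(0)
        f = 0.3
        m = pd.DataFrame(
            (rng.random((30, 200)) < f).astype(int),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(200)],
        )
        rates = mx.estimate_background(m)
        # cell probabilities hover around the realized frequency
        assert abs(rates.p.to_numpy().mean() - m.to_numpy().mean()) < 1e-6
        assert rates.p.to_numpy().std() < 0.15

    def test_identity_matrix_margins_match(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], columns=["x", "y"])
        rates = mx.estimate_background(m)
        np.testing.assert_allclose(rates.p.sum(axis=1), [1, 1], atol=1e-6)
        np.testing.assert_allclose(rates.p.sum(axis=0), [1, 1], atol=1e-6)

    def test_all_zero_row_dropped_with_warning(self):
        m = pd.DataFrame(
            [[1, 0, 1], [0, 0, 0], [0, 1, 1]],
            index=["a", "z", "b"],
            columns=["x", "y", "w"],
        )
        with pytest.warns(UserWarning, match="all-zero/all-one gene"):
            rates = mx.estimate_background(m)
        assert "z" not in rates.p.index

    def test_non_binary_matrix_rejected(self):
        m = pd.DataFrame([[2, 0], [0, 1]], index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValueError, match="binary"):
            mx.estimate_background(m)

    def test_margins_match_on_random_matrix(self, toy_mutation_matrix):
        rates = mx.estimate_background(toy_mutation_matrix)
        np.testing.assert_allclose(
            rates.p.sum(axis=1), toy_mutation_matrix.sum(axis=1), atol=1e-5
        )
        np.testing.assert_allclose(
            rates.p.sum(axis=0), toy_mutation_matrix.sum(axis=0), atol=1e-5
        )


class TestPoissonBinomialTail:
    def test_hand_case_three_samples(self):
        # p_a = p_b = 0.5 each sample -> q = 0.25; P(C=0) = 0.75^3
        assert mx.poisson_binomial_lower_tail([0.25] * 3, 0) == pytest.approx(0.421875)

    def test_full_tail_is_one(self):
        q = [0.3, 0.7, 0.1]
        assert mx.poisson_binomial_lower_tail(q, 3) == 1.0

    def test_degenerate_all_zero_probabilities(self):
        assert mx.poisson_binomial_lower_tail([0.0] * 5, 0) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        q = rng.random(n)
        k = int(rng.integers(0, n + 1))
        assert mx.poisson_binomial_lower_tail(q, k) == pytest.approx(
            brute_force_lower_tail(q, k), abs=1e-12
        )


class TestExclusivityTest:
    def test_hand_case_via_estimated_background(self):
        # rows with identical margins on 3 samples: estimated p = 0.5 everywhere
        m = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1], [1, 0, 1], [0, 1, 1]],
            index=list("abcd"),
            columns=["x", "y", "z"],
        )
        rates = mx.BackgroundRates(
            pd.DataFrame(0.5, index=m.index, columns=m.columns)
        )
        r = mx.exclusivity_test("a", "b", m, rates)
        assert r.expected_co == pytest.approx(0.75)
        assert r.n_co == 1
        # P(C <= 1) with q = 0.25 thrice
        assert r.p_value == pytest.approx(brute_force_lower_tail([0.25] * 3, 1))

    def test_co_mutated_everywhere_gives_p_one(self):
        m = pd.DataFrame(
            [[1, 1, 1], [1, 1, 1]], index=["a", "b"], columns=["x", "y", "z"]
        )
        rates = mx.BackgroundRates(
            pd.DataFrame(0.9, index=m.index, columns=m.columns)
        )
        assert mx.exclusivity_test("a", "b", m, rates).p_value == pytest.approx(1.0)

    def test_missing_gene_raises(self, toy_mutation_matrix):
        rates = mx.estimate_background(toy_mutation_matrix)
        with pytest.raises(KeyError):
            mx.exclusivity_test("g0", "nope", toy_mutation_matrix, rates)


class TestPermutationOracle:
    def test_identity_matrix_has_one_alternative_configuration(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], columns=["x", "y"])
        seen = set()
        rng = np.random.default_rng(0)
        rows = [{0}, {1}]
        for _ in range(50):
            mx._curveball_step(rows, rng)
            seen.add((frozenset(rows[0]), frozenset(rows[1])))
        assert seen == {(frozenset({0}), frozenset({1})), (frozenset({1}), frozenset({0}))}

    def test_swaps_preserve_margins(self, toy_mutation_matrix):
        x = toy_mutation_matrix.to_numpy()
        rows = [set(np.flatnonzero(x[i])) for i in range(x.shape[0])]
        row_sums = [len(r) for r in rows]
        col_counts = np.zeros(x.shape[1], dtype=int)
        for r in rows:
            for j in r:
                col_counts[j] += 1
        rng = np.random.default_rng(1)
        for _ in range(500):
            mx._curveball_step(rows, rng)
        assert [len(r) for r in rows] == row_sums
        after = np.zeros_like(col_counts)
        for r in rows:
            for j in r:
                after[j] += 1
        np.testing.assert_array_equal(after, col_counts)

    def test_nested_matrix_returns_one_with_warning(self):
        m = pd.DataFrame(
            [[1, 1], [1, 0]], index=["a", "b"], columns=["x", "y"]
        )
        with pytest.warns(UserWarning, match="checkerboard"):
            assert mx.permutation_oracle(m, ("a", "b"), n_perm=100, seed=0) == 1.0

    def test_too_few_permutations_rejected(self, toy_mutation_matrix):
        with pytest.raises(ValueError, match="n_perm"):
            mx.permutation_oracle(toy_mutation_matrix, ("g0", "g1"), n_perm=10)


class TestAdjustAndFlag:
    def make(self, pvals):
        return [
            mx.MutexResult(f"a{i}", f"b{i}", 0, 1.0, p) for i, p in enumerate(pvals)
        ]

    def test_single_pair_bh_identity(self):
        res = mx.adjust_and_flag(self.make([0.04]), threshold=0.15)
        assert res[0].p_adjust == pytest.approx(0.04)
        assert res[0].passed

    def test_bh_step_up_by_hand(self):
        res = mx.adjust_and_flag(self.make([0.01, 0.02, 0.03]))
        assert [r.p_adjust for r in res] == pytest.approx([0.03, 0.03, 0.03])

    def test_all_null_pvalues_fail(self):
        res = mx.adjust_and_flag(self.make([1.0, 1.0, 1.0]), threshold=0.15)
        assert not any(r.passed for r in res)

    def test_stricter_methods_threshold_available(self):
        res = mx.adjust_and_flag(self.make([0.12]), threshold=0.1)
        assert not res[0].passed

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            mx.adjust_and_flag([])


def test_power_against_planted_exclusivity():
    """Planted pairs (excl_factor 0.1, frequencies 0.1-0.3, n=300) are rejected
    at p_adjust < 0.15 in at least 80% of simulations."""
    rng = np.random.default_rng(42)
    n_samp, n_rep = 300, 100
    hits = 0
    for _ in range(n_rep):
        ra, rb = rng.uniform(0.1, 0.3, 2)
        burden = rng.lognormal(0, 0.25, n_samp)
        pa = np.clip(ra * burden, 1e-4, 0.95)
        pb = np.clip(rb * burden, 1e-4, 0.95)
        p_both = 0.1 * pa * pb
        u = rng.random(n_samp)
        a = u < pa
        b = (u < p_both) | ((u >= pa) & (u < pa + pb - p_both))
        n_co = int((a & b).sum())
        p = mx.poisson_binomial_lower_tail(pa * pb, n_co)
        hits += p < 0.15  # single-pair family: p_adjust = p
    assert hits / n_rep >= 0.8
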