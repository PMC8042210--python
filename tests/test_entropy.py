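"""Unit, oracle and property tests for approximations and entropies."""

import math

import numpy as np
import pytest

from fsace.entropy import (
    SubsetEntropyEvaluator,
    approximate_accuracy,
    approximate_conditional_entropy,
    conditional_entropy,
    entropy_report,
    granulation_for_subset,
    iea,
    iia,
    is_reduction,
    lower_approximation,
    upper_approximation,
)
from fsace.granulation import DecisionTable

from conftest import (
    as_decision_partition,
    as_structure,
    oracle_accuracy,
    oracle_ace,
    oracle_conditional_entropy,
    oracle_lower,
    oracle_upper,
    random_decision_partition,
    random_partition,
)


def singleton_structure(n, bins=4):
    return as_structure([frozenset([i]) for i in range(n)], list(range(n)), bins)


def universal_structure(n, bins=4):
    return as_structure([frozenset(range(n))], [0] * n, bins)


class TestApproximations:
    def test_singleton_granules_fix_any_set(self, rng):
        G = singleton_structure(9)
        X = {1, 4, 7}
        assert lower_approximation(G, X) == frozenset(X)
        assert upper_approximation(G, X) == frozenset(X)

    def test_universal_granule(self):
        G = universal_structure(6)
        assert lower_approximation(G, {0, 1}) == frozenset()
        assert upper_approximation(G, {0, 1}) == frozenset(range(6))

    def test_against_oracle(self, rng):
        for _ in range(50):
            n = 12
            granules, granule_of = random_partition(rng, n)
            G = as_structure(granules, granule_of)
            X = frozenset(
                int(i) for i in np.nonzero(rng.random(n) < 0.4)[0]
            )
            assert lower_approximation(G, X) == oracle_lower(granules, granule_of, X)
            assert upper_approximation(G, X) == oracle_upper(granules, granule_of, X)

    def test_upper_contains_lower_and_x(self, rng):
        for _ in range(30):
            granules, granule_of = random_partition(rng, 10)
            G = as_structure(granules, granule_of)
            X = frozenset(int(i) for i in rng.choice(10, size=4, replace=False))
            lo = lower_approximation(G, X)
            up = upper_approximation(G, X)
            assert lo <= up
            assert X <= up


class TestApproximateAccuracy:
    def test_singletons_give_one(self, rng):
        G = singleton_structure(8)
        assert approximate_accuracy(G, {2, 5}) == 1.0

    def test_universal_proper_subset_gives_zero(self):
        G = universal_structure(7)
        assert approximate_accuracy(G, {0, 3}) == 0.0

    def test_worked_example(self):
        # granules {0,1},{2,3},{4,5}, X={0,1,2}: lower={0,1}, upper={0,1,2,3}
        G = as_structure(
            [frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})],
            [0, 0, 1, 1, 2, 2],
        )
        assert approximate_accuracy(G, {0, 1, 2}) == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="approximate accuracy undefined"):
            approximate_accuracy(singleton_structure(4), set())

    def test_bounds_and_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 16))
            granules, granule_of = random_partition(rng, n)
            G = as_structure(granules, granule_of)
            k = int(rng.integers(1, n + 1))
            X = frozenset(int(i) for i in rng.choice(n, size=k, replace=False))
            a = approximate_accuracy(G, X)
            assert 0.0 <= a <= 1.0
            assert a == oracle_accuracy(granules, granule_of, X)


class TestConditionalEntropy:
    def test_singleton_granules_give_zero(self, rng):
        G = singleton_structure(6)
        classes, _ = random_decision_partition(rng, 6)
        assert conditional_entropy(G, as_decision_partition(classes)) == 0.0

    def test_theorem_maximum(self):
        # universal granule + singleton classes: n*log2(n) bits
        for n in (2, 4, 8):
            G = universal_structure(n)
            P = as_decision_partition([frozenset([i]) for i in range(n)])
            assert conditional_entropy(G, P) == pytest.approx(
                n * math.log2(n), abs=1e-12
            )

    def test_against_double_loop_oracle(self, rng):
        for _ in range(50):
            n = 10
            granules, granule_of = random_partition(rng, n)
            classes, _ = random_decision_partition(rng, n)
            got = conditional_entropy(
                as_structure(granules, granule_of), as_decision_partition(classes)
            )
            want = oracle_conditional_entropy(
                granules, granule_of, [frozenset(c) for c in classes]
            )
            assert got == pytest.approx(want, abs=1e-12)


class TestApproximateConditionalEntropy:
    def test_zero_iff_granules_class_pure(self, rng):
        # both directions, exhaustive granule checks at small n
        for _ in range(200):
            n = int(rng.integers(3, 13))
            granules, granule_of = random_partition(rng, n)
            classes, class_of = random_decision_partition(rng, n)
            G = as_structure(granules, granule_of)
            P = as_decision_partition(classes)
            pure = all(
                len({class_of[i] for i in g}) == 1 for g in granules
            )
            h = approximate_conditional_entropy(G, P)
            assert (h < 1e-12) == pure

    def test_theorem_maximum_weight_is_one(self):
        n = 4
        G = universal_structure(n)
        P = as_decision_partition([frozenset([i]) for i in range(n)])
        assert approximate_conditional_entropy(G, P) == pytest.approx(8.0, abs=1e-12)

    def test_against_compositional_oracle(self, rng):
        for _ in range(50):
            n = 10
            granules, granule_of = random_partition(rng, n)
            classes, _ = random_decision_partition(rng, n)
            got = approximate_conditional_entropy(
                as_structure(granules, granule_of), as_decision_partition(classes)
            )
            want = oracle_ace(
                granules, granule_of, [frozenset(c) for c in classes]
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_bound_chain(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 31))
            granules, granule_of = random_partition(rng, n)
            classes, _ = random_decision_partition(rng, n)
            G = as_structure(granules, granule_of)
            P = as_decision_partition(classes)
            h_ace = approximate_conditional_entropy(G, P)
            h_cond = conditional_entropy(G, P)
            assert -1e-12 <= h_ace <= h_cond + 1e-12
            assert h_cond <= n * math.log2(n) + 1e-9


class TestSubsetPipeline:
    def test_empty_subset_is_universal(self, rng):
        t = DecisionTable(rng.random((6, 3)), np.array(["a", "b"] * 3))
        G = granulation_for_subset(t, (), 0.5, 4)
        assert len(G.granules) == 1

    def test_report_fields(self, rng):
        t = DecisionTable(rng.random((8, 3)), np.array(["a", "b"] * 4))
        rep = entropy_report(t, (0, 1, 2), 0.5, 4)
        assert 0.0 <= rep.h_ace <= rep.h_conditional + 1e-12
        assert len(rep.per_class_accuracy) == 2
        assert all(0.0 <= a <= 1.0 for a in rep.per_class_accuracy)

    def test_cache_does_not_change_values(self, rng):
        t = DecisionTable(rng.random((10, 4)), np.array(["a", "b"] * 5))
        cached = SubsetEntropyEvaluator(t, 0.4, 4, use_cache=True)
        plain = SubsetEntropyEvaluator(t, 0.4, 4, use_cache=False)
        for subset in [(), (0,), (1, 2), (0, 1, 2, 3), (0,), ()]:
            assert cached.h_ace(subset) == plain.h_ace(subset)


class TestImportance:
    def _table(self, rng, n=12, m=4):
        return DecisionTable(
            rng.random((n, m)), np.array(["a", "b", "c"] * (n // 3))
        )

    def test_iia_constant_attribute_is_zero(self, rng):
        # a constant column adds nothing to any pairwise distance, so
        # removing it leaves every granulation (hence the entropy) unchanged
        v = rng.random((9, 3))
        v = np.column_stack([v, np.full(9, 0.5)])
        t = DecisionTable(v, np.array(["a", "b", "c"] * 3))
        assert iia(t, 3, 0.4, 4) == pytest.approx(0.0, abs=1e-12)

    def test_iia_duplicate_attribute_can_rescale_distances(self, rng):
        # a duplicated column doubles its squared-distance contribution;
        # the binned granulation may shift, so IIA need not vanish — it
        # must still equal the compositional difference of entropies
        v = rng.random((9, 3))
        v = np.column_stack([v, v[:, 0]])
        t = DecisionTable(v, np.array(["a", "b", "c"] * 3))
        ev = SubsetEntropyEvaluator(t, 0.4, 4)
        want = ev.h_ace(frozenset({0, 1, 2})) - ev.h_ace(frozenset({0, 1, 2, 3}))
        assert iia(t, 3, 0.4, 4) == pytest.approx(want, abs=1e-12)

    def test_iia_matches_compositional_oracle(self, rng):
        t = self._table(rng)
        ev = SubsetEntropyEvaluator(t, 0.4, 4)
        full = frozenset(range(4))
        for c in range(4):
            want = ev.h_ace(full - {c}) - ev.h_ace(full)
            assert iia(t, c, 0.4, 4) == pytest.approx(want, abs=1e-12)

    def test_iia_positive_for_sole_separating_attribute(self):
        # attribute 0 separates the classes; attribute 1 is constant
        v = np.array([[0.0, 0.5], [0.05, 0.5], [1.0, 0.5], [0.95, 0.5]])
        t = DecisionTable(v, np.array(["a", "a", "b", "b"]))
        assert iia(t, 0, 0.5, 2) > 0

    def test_iia_single_attribute_rejected(self, rng):
        t = DecisionTable(rng.random((4, 1)), np.array(["a", "b", "a", "b"]))
        with pytest.raises(ValueError, match="cannot remove the only attribute"):
            iia(t, 0, 0.4, 4)

    def test_iea_constant_attribute_is_zero(self, rng):
        # adding a zero-range column leaves all distances, hence the
        # granulation, unchanged
        v = rng.random((9, 3))
        v = np.column_stack([v, np.full(9, 0.3)])
        t = DecisionTable(v, np.array(["a", "b", "c"] * 3))
        assert iea(t, {1}, 3, 0.4, 4) == pytest.approx(0.0, abs=1e-12)

    def test_iea_already_selected_rejected(self, rng):
        t = self._table(rng)
        with pytest.raises(ValueError, match="attribute already selected"):
            iea(t, {0, 1}, 1, 0.4, 4)

    def test_iea_matches_compositional_oracle(self, rng):
        t = self._table(rng)
        ev = SubsetEntropyEvaluator(t, 0.4, 4)
        for B in [frozenset(), frozenset({0}), frozenset({1, 3})]:
            for d in set(range(4)) - B:
                want = ev.h_ace(B) - ev.h_ace(B | {d})
                assert iea(t, B, d, 0.4, 4) == pytest.approx(want, abs=1e-12)

    def test_iea_reaching_zero_entropy_equals_h_of_b(self):
        # attribute 1 alone makes every granule class-pure
        v = np.array(
            [[0.5, 0.0], [0.5, 0.02], [0.5, 1.0], [0.5, 0.98],
             [0.5, 0.01], [0.5, 0.99]]
        )
        t = DecisionTable(v, np.array(["a", "a", "b", "b", "a", "b"]))
        ev = SubsetEntropyEvaluator(t, 0.5, 2)
        h_b = ev.h_ace(frozenset({0}))
        assert ev.h_ace(frozenset({0, 1})) == pytest.approx(0.0, abs=1e-12)
        assert iea(t, {0}, 1, 0.5, 2) == pytest.approx(h_b, abs=1e-12)


class TestIsReduction:
    def test_duplicate_superset_is_not_a_reduction(self):
        v = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0], [0.9, 0.9]])
        t = DecisionTable(v, np.array(["a", "a", "b", "b"]))
        # both columns identical: either alone preserves entropy, both is redundant
        assert not is_reduction(t, {0, 1}, 0.5, 2)
        assert is_reduction(t, {0}, 0.5, 2)

    def test_empty_subset_rejected(self, rng):
        t = DecisionTable(rng.random((4, 2)), np.array(["a", "b", "a", "b"]))
        with pytest.raises(ValueError):
            is_reduction(t, set(), 0.5, 4)


class TestTheorem22Monotonicity:
    def test_empirical_monotonicity_logged(self, rng, capsys):
        """Adding attributes should not raise H_ace; violations are counted,
        reported and tolerated (bin membership is not monotone in distance)."""
        violations = 0
        trials = 0
        for _ in range(40):
            n = int(rng.integers(6, 15))
            t = DecisionTable(
                rng.random((n, 4)),
                np.array(["a", "b"] * (n // 2) + ["a"] * (n % 2)),
            )
            ev = SubsetEntropyEvaluator(t, float(rng.uniform(0.1, 1.0)), 4)
            subsets = [frozenset({0}), frozenset({0, 1}), frozenset({0, 1, 2}),
                       frozenset({0, 1, 2, 3})]
            hs = [ev.h_ace(B) for B in subsets]
            for a, b in zip(hs, hs[1:]):
                trials += 1
                if b > a + 1e-9:
                    violations += 1
        print(f"monotonicity violations: {violations}/{trials}")
        assert trials > 0  # the check ran; violations are recorded, not asserted
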