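import numpy as np
import pytest

import hopwave as hw
from hopwave.classification import (
    COMPARISONS,
    ClassificationResult,
    ComparisonSpec,
    knn_loocv,
    run_comparisons,
    vectorize,
)
from hopwave.errors import ConfigurationError

TRIAL_CV = ComparisonSpec("ACLR_Contra vs Control_Idx", cv_unit="trial")


def brute_force_loocv(X, labels):
    """Independent 1-NN LOOCV oracle: explicit distances, lowest-index ties."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    correct = 0
    for i in range(n):
        best_j, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            if d < best_d:  # strict: first (lowest) index wins ties
                best_d, best_j = d, j
        correct += labels[best_j] == labels[i]
    return correct


class TestKnnLoocvToys:
    def test_separated_clusters_fully_correct(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = ["A", "A", "B", "B"]
        res = knn_loocv(X, labels, TRIAL_CV)
        assert (res.n_correct, res.n_total) == (4, 4)
        assert res.rate_percent == 100.0

    def test_alternating_labels_fully_wrong(self):
        # ties at equal distance resolve to the lowest index, so every
        # point's winning neighbor carries the opposite label
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        labels = ["A", "B", "A", "B"]
        res = knn_loocv(X, labels, TRIAL_CV)
        assert (res.n_correct, res.n_total) == (0, 4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            knn_loocv(np.array([[0.0]]), ["A"], TRIAL_CV)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            knn_loocv(np.array([[0.0], [1.0]]), ["A", "A"], TRIAL_CV)

    def test_duplicate_vector_in_both_classes_warns(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
        labels = ["A", "B", "A", "B"]
        with pytest.warns(RuntimeWarning, match="leakage"):
            knn_loocv(X, labels, TRIAL_CV)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_battery(self):
        # >= 100 random labeled point sets of <= 8 points, exact agreement
        rng = np.random.default_rng(7)
        for _ in range(120):
            n = int(rng.integers(4, 9))
            d = int(rng.integers(1, 5))
            X = np.round(rng.standard_normal((n, d)) * 2, 1)  # rounding forces ties
            labels = rng.choice(["A", "B"], size=n).tolist()
            if len(set(labels)) < 2:
                labels[0] = "A" if labels[0] == "B" else "B"
            expected = brute_force_loocv(X, labels)
            import warnings

            with warnings.catch_warnings():
                # rounded random points may coincide across classes
                warnings.simplefilter("ignore", RuntimeWarning)
                got = knn_loocv(X, labels, TRIAL_CV).n_correct
            assert got == expected

    def test_deterministic(self, rng):
        X = rng.standard_normal((20, 6))
        labels = (["A"] * 10) + (["B"] * 10)
        r1 = knn_loocv(X, labels, TRIAL_CV)
        r2 = knn_loocv(X, labels, TRIAL_CV)
        assert (r1.n_correct, r1.n_total) == (r2.n_correct, r2.n_total)


class TestPermutationNull:
    def test_mean_rate_near_chance_under_label_permutation(self):
        rng = np.random.default_rng(42)
        n = 60
        X = rng.standard_normal((n, 8))
        rates = []
        for _ in range(200):
            labels = rng.permutation(["A"] * (n // 2) + ["B"] * (n // 2))
            rates.append(knn_loocv(X, labels, TRIAL_CV).rate_percent)
        assert abs(np.mean(rates) - 50.0) < 2.0


class TestVectorize:
    def _pattern(self, rng):
        return hw.NormalizedPattern(
            muscle="GM", values=rng.standard_normal((14, 300)), band_freqs=np.arange(14.0)
        )

    def test_whole_hop_length(self, rng):
        assert vectorize(self._pattern(rng), "all").shape == (4200,)

    def test_phase_slice_length_and_content(self, rng):
        p = self._pattern(rng)
        v = vectorize(p, "take-off")
        assert v.shape == (1400,)
        assert np.array_equal(v, p.values[:, :100].ravel())

    def test_unknown_phase_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            vectorize(self._pattern(rng), "flight")


class TestResultInvariants:
    def test_rate_rounded_to_one_decimal(self):
        res = ClassificationResult("GM", COMPARISONS[0].name, "all", 43, 62)
        assert res.rate_percent == 69.4

    def test_counts_validated(self):
        with pytest.raises(ConfigurationError):
            ClassificationResult("GM", COMPARISONS[0].name, "all", 5, 4)


class TestRunComparisons:
    def test_grid_over_small_cohort(self, small_cohort):
        _, patterns = small_cohort
        results = run_comparisons(patterns, COMPARISONS)
        assert len(results) == 3 * 7
        # comparison sample sizes follow the trial-limb counting convention
        by_comparison = {r.comparison: r.n_total for r in results}
        assert by_comparison["Control_Idx vs Control_Contra"] == 3 * 2 * 3
        assert by_comparison["ACLR_Sx vs ACLR_Contra"] == 3 * 2 * 3
        assert by_comparison["ACLR_Contra vs Control_Idx"] == 3 * 3 + 3 * 3

    def test_empty_class_rejected(self, small_cohort):
        _, patterns = small_cohort
        controls_only = [p for p in patterns if p.group == "Control"]
        with pytest.raises(ConfigurationError):
            run_comparisons(controls_only, [COMPARISONS[1]])
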