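"""PE / agreement, bootstrap intervals, Chang CV and APE."""

import numpy as np
import pytest
from scipy import stats

from ageval import (
    CohortConfig,
    ReaderProfile,
    UndefinedStatisticError,
    ape,
    bootstrap_ci,
    chang_cv,
    classwise_misclassification,
    generate_cohort,
    percent_agreement,
    percent_error,
    simulate_reader_estimates,
)


class TestPercentError:
    def test_identity_gives_zero(self):
        assert percent_error([1, 2, 3], [1, 2, 3]) == 0.0

    def test_direct_fraction(self):
        assert percent_error([1, 1, 1, 1], [1, 1, 1, 2]) == 25.0

    def test_pooled_study_counts(self):
        """Pooled over two readers with 40/52 and 36/54 correct: 71.7% agreement."""
        true_ages = [2] * 52 + [2] * 54
        est = [2] * 40 + [3] * 12 + [2] * 36 + [3] * 18
        assert percent_agreement(true_ages, est) == pytest.approx(100 * 76 / 106)
        assert percent_agreement(true_ages, est) == pytest.approx(71.7, abs=0.05)

    def test_unreadable_excluded_from_numerator_and_denominator(self):
        # 1 wrong of 2 readable; the abstention changes nothing
        assert percent_error([1, 2, 3], [1, None, 4]) == 50.0

    def test_all_unreadable_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            percent_error([1, 2], [None, None])

    def test_pooled_pe_is_read_weighted_mean_of_reader_pes(self):
        rng = np.random.default_rng(0)
        true_ages = list(rng.integers(1, 4, size=40))
        per_reader = []
        for _ in range(3):
            est = [
                None if rng.random() < 0.2 else (t + 1 if rng.random() < 0.3 else t)
                for t in true_ages
            ]
            per_reader.append(est)
        pooled = percent_error(true_ages * 3, sum(per_reader, []))
        weights = [sum(e is not None for e in est) for est in per_reader]
        pes = [percent_error(true_ages, est) for est in per_reader]
        weighted = sum(w * p for w, p in zip(weights, pes)) / sum(weights)
        assert pooled == pytest.approx(weighted)


class TestBootstrap:
    def test_constant_statistic_gives_zero_width(self):
        lo, hi = bootstrap_ci(lambda u: 42.0, list(range(10)), b=50, seed=0)
        assert lo == hi == 42.0

    def test_quantiles_ordered(self):
        units = list(np.random.default_rng(1).normal(size=30))
        lo, hi = bootstrap_ci(lambda u: float(np.mean(u)), units, b=200, seed=2)
        assert lo <= hi

    def test_reproducible_given_seed(self):
        units = list(range(20))
        a = bootstrap_ci(lambda u: float(np.mean(u)), units, b=100, seed=7)
        b = bootstrap_ci(lambda u: float(np.mean(u)), units, b=100, seed=7)
        assert a == b

    def test_undefined_statistic_redrawn_then_capped(self):
        def always_undefined(u):
            raise UndefinedStatisticError("nope")

        with pytest.raises(UndefinedStatisticError, match="consecutive"):
            bootstrap_ci(always_undefined, [1, 2, 3], b=5, seed=0,
                         max_redraws_per_resample=3)

    def test_large_b_matches_exact_binomial_quantiles(self):
        """On a 0/1 statistic the percentile bootstrap converges to the
        binomial quantiles of the resampled success count."""
        units = np.array([1.0] * 5 + [0.0] * 15)  # empirical p = 0.25, n = 20
        lo, hi = bootstrap_ci(lambda u: float(np.mean(u)), units, b=20000, seed=3)
        exact_lo = stats.binom.ppf(0.025, 20, 0.25) / 20
        exact_hi = stats.binom.ppf(0.975, 20, 0.25) / 20
        assert lo == pytest.approx(exact_lo, abs=1 / 20)
        assert hi == pytest.approx(exact_hi, abs=1 / 20)


class TestLengthPrecision:
    def test_zero_dispersion_gives_zero(self):
        assert chang_cv([[10.0, 10.0], [12.0, 12.0]], [10.0, 12.0]) == 0.0
        assert ape([[10.0, 10.0]], [10.0]) == 0.0

    def test_cv_reader_mean_reference(self):
        # one fish, readings {10, 12}: sd = sqrt(2), ref = 11
        assert chang_cv([[10.0, 12.0]]) == pytest.approx(100 * np.sqrt(2) / 11)
        assert chang_cv([[10.0, 12.0]]) == pytest.approx(12.86, abs=0.005)

    def test_cv_true_length_reference(self):
        # readings {9, 11} with true length 10: sd = sqrt(2), ref = 10
        assert chang_cv([[9.0, 11.0]], [10.0]) == pytest.approx(100 * np.sqrt(2) / 10)
        assert chang_cv([[9.0, 11.0]], [10.0]) == pytest.approx(14.14, abs=0.005)

    def test_ape_hand_calculation(self):
        assert ape([[10.0, 12.0]]) == pytest.approx(100 * 2 / (2 * 11))
        assert ape([[10.0, 12.0]]) == pytest.approx(9.09, abs=0.005)

    def test_cv_invariant_to_reader_order(self):
        readings = [[10.0, 12.0, 11.0], [14.0, 13.0]]
        shuffled = [[11.0, 10.0, 12.0], [13.0, 14.0]]
        assert chang_cv(readings) == pytest.approx(chang_cv(shuffled))

    def test_appending_zero_dispersion_fish_rescales_exactly(self):
        readings = [[10.0, 12.0], [13.0, 15.0]]
        refs = [11.0, 14.0]
        base = chang_cv(readings, refs)
        grown = chang_cv(readings + [[9.0, 9.0]], refs + [9.0])
        assert grown == pytest.approx(base * 2 / 3)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            chang_cv([[1.0, 2.0]], [0.0])

    def test_single_reading_fish_excluded(self):
        assert chang_cv([[10.0], [10.0, 12.0]]) == pytest.approx(chang_cv([[10.0, 12.0]]))
        with pytest.raises(UndefinedStatisticError):
            chang_cv([[10.0]])


class TestClasswise:
    def test_study_fractions_reported_exactly(self):
        # 2 misclassified of 126 one-sea-winter fish, 11 of 128 older fish
        true_ages = [1] * 126 + [2] * 128
        est = list(true_ages)
        est[0] = est[1] = 2
        for i in range(126, 137):
            est[i] = 3
        out = classwise_misclassification(
            true_ages, {"R1": est}, {1: "1SW", 2: "MSW"}
        )
        assert out["1SW"] == {"n_misclassified": 2, "n_fish": 126,
                              "percent": pytest.approx(100 * 2 / 126)}
        assert out["MSW"]["n_misclassified"] == 11
        assert out["MSW"]["percent"] == pytest.approx(100 * 11 / 128)

    def test_no_errors_gives_zero_everywhere(self):
        out = classwise_misclassification(
            [1, 2, 2], {"R1": [1, 2, 2], "R2": [1, None, 2]}, {1: "a", 2: "b"}
        )
        assert all(v["percent"] == 0.0 for v in out.values())

    def test_any_wrong_reader_flags_the_fish(self):
        out = classwise_misclassification(
            [2], {"R1": [2], "R2": [3]}, {2: "MSW"}
        )
        assert out["MSW"]["n_misclassified"] == 1


def test_pe_recovers_configured_misclassification_probability():
    """End-to-end parameter recovery: simulated PE within 3 binomial SEs."""
    p = 0.10
    fish = generate_cohort(CohortConfig(n_fish=254, seed=31))
    profiles = [
        ReaderProfile(f"R{i}", sea_misclass_prob_by_class={"1SW": p, "MSW": p})
        for i in (1, 2, 3)
    ]
    reads = simulate_reader_estimates(fish, profiles, seed=32)
    truth = {f.fish_id: f.true_sea_age for f in fish}
    pe = percent_error(
        [truth[r.fish_id] for r in reads], [r.sea_age_est for r in reads]
    )
    n = len(reads)
    se = 100 * np.sqrt(p * (1 - p) / n)
    assert abs(pe - 100 * p) <= 3 * se
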