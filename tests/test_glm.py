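"""Binomial misclassification GLMs and all-subsets AIC selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ageval import (
    CohortConfig,
    ReaderAgeEstimate,
    all_subsets_aic,
    build_misclassification_response,
    fit_binomial_glm,
    generate_cohort,
)
from ageval.glm import GlmFit, _rank_key, build_design_matrix


class TestResponse:
    def _fish(self):
        return generate_cohort(CohortConfig(n_fish=4, fw_known_prob=1.0, seed=2))

    def test_all_correct_gives_zero(self):
        fish = self._fish()
        f = fish[0]
        reads = [
            ReaderAgeEstimate(f.fish_id, f"R{i}", None, f.true_sea_age) for i in range(3)
        ]
        out = build_misclassification_response(fish, reads, "sea")
        assert out.loc[out.fish_id == f.fish_id, "response"].item() == 0

    def test_one_wrong_reader_gives_one(self):
        fish = self._fish()
        f = fish[0]
        reads = [
            ReaderAgeEstimate(f.fish_id, "R1", None, f.true_sea_age),
            ReaderAgeEstimate(f.fish_id, "R2", None, f.true_sea_age + 1),
        ]
        out = build_misclassification_response(fish, reads, "sea")
        assert out.loc[out.fish_id == f.fish_id, "response"].item() == 1

    def test_abstention_is_not_an_error(self):
        fish = self._fish()
        f = fish[0]
        truth = f.true_fw_age
        reads = [
            ReaderAgeEstimate(f.fish_id, "R1", truth, 1),
            ReaderAgeEstimate(f.fish_id, "R2", truth, 1),
            ReaderAgeEstimate(f.fish_id, "R3", None, 1),
        ]
        out = build_misclassification_response(fish, reads, "fw")
        assert out.loc[out.fish_id == f.fish_id, "response"].item() == 0

    def test_fish_without_readable_reads_excluded(self):
        fish = self._fish()
        reads = [ReaderAgeEstimate(fish[0].fish_id, "R1", None, fish[0].true_sea_age)]
        out = build_misclassification_response(fish, reads, "sea")
        assert len(out) == 1

    def test_age_classes_aggregated(self):
        fish = generate_cohort(CohortConfig(n_fish=100, fw_known_prob=1.0, seed=5))
        reads = [ReaderAgeEstimate(f.fish_id, "R1", 2, f.true_sea_age) for f in fish]
        sea = build_misclassification_response(fish, reads, "sea")
        assert set(sea.age_class) <= {"1SW", "MSW"}
        fw = build_misclassification_response(fish, reads, "fw")
        assert set(fw.age_class) <= {"1-2", "3-5"}


class TestFit:
    def test_intercept_only_closed_form(self):
        data = pd.DataFrame({"response": [1] * 25 + [0] * 75})
        fit = fit_binomial_glm(data, ())
        assert fit.coefficients["Intercept"] == pytest.approx(math.log(25 / 75), abs=1e-8)
        assert fit.loglik == pytest.approx(25 * math.log(0.25) + 75 * math.log(0.75), abs=1e-8)
        assert fit.aic == pytest.approx(114.47, abs=0.005)

    def test_aic_identity(self):
        data = pd.DataFrame(
            {"response": [0, 1, 0, 1, 1, 0, 0, 1, 0, 0],
             "smolt_length": [12, 13, 14, 15, 13, 12, 16, 14, 13, 15]}
        )
        fit = fit_binomial_glm(data, ("smolt_length",))
        assert fit.aic == pytest.approx(2 * len(fit.coefficients) - 2 * fit.loglik)

    def test_null_deviance_is_binary_entropy(self):
        # balanced responses: deviance = 2 n H(1/2) = 2 n ln 2
        n = 24
        data = pd.DataFrame({"response": [0, 1] * (n // 2)})
        fit = fit_binomial_glm(data, ())
        assert -2 * fit.loglik == pytest.approx(2 * n * math.log(2), abs=1e-8)

    def test_irls_matches_direct_likelihood_maximization(self):
        """Brute-force oracle: numerically maximize the binomial log-likelihood."""
        rng = np.random.default_rng(8)
        n = 60
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        eta = -0.5 + 0.8 * x1 - 0.4 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        data = pd.DataFrame({"response": y, "smolt_length": x1, "adult_length": x2})
        fit = fit_binomial_glm(data, ("smolt_length", "adult_length"))

        X = np.column_stack([np.ones(n), x1, x2])

        def nll(beta):
            e = X @ beta
            return float(np.sum(np.log1p(np.exp(e))) - y @ e)

        res = optimize.minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        names = ["Intercept", "smolt_length", "adult_length"]
        for name, b in zip(names, res.x):
            assert fit.coefficients[name] == pytest.approx(b, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_perfect_separation_flagged_degenerate(self):
        data = pd.DataFrame(
            {"response": [0] * 12, "smolt_length": np.linspace(12, 16, 12)}
        )
        fit = fit_binomial_glm(data, ("smolt_length",))
        assert fit.degenerate

    def test_design_matrix_dummy_codes_against_first_level(self):
        data = pd.DataFrame(
            {"response": [0, 1, 0, 1], "smolt_year": [2016, 2017, 2018, 2016],
             "sex": ["F", "M", "F", "M"]}
        )
        X = build_design_matrix(data, ("smolt_year", "sex"))
        assert "smolt_year[2016]" not in X.columns  # earliest year is the reference
        assert {"smolt_year[2017]", "smolt_year[2018]", "sex[M]"} <= set(X.columns)


class TestAllSubsets:
    def test_enumeration_count_without_interaction(self):
        rng = np.random.default_rng(3)
        n = 80
        data = pd.DataFrame(
            {
                "response": rng.integers(0, 2, n),
                "smolt_length": rng.normal(13.7, 1.1, n),
                "adult_length": rng.normal(69, 10, n),
                "sex": rng.choice(["F", "M"], n),
            }
        )
        best, table = all_subsets_aic(data, ("smolt_length", "adult_length", "sex"))
        assert len(table) == 2 ** 3

    def test_marginality_respected_with_interaction(self):
        rng = np.random.default_rng(4)
        n = 120
        data = pd.DataFrame(
            {
                "response": rng.integers(0, 2, n),
                "age_class": rng.choice(["1SW", "MSW"], n),
                "adult_length": rng.normal(69, 10, n),
            }
        )
        best, table = all_subsets_aic(
            data, ("age_class", "adult_length"), interaction=("age_class", "adult_length")
        )
        # 4 main-effect subsets + 1 with the interaction added to the full set
        assert len(table) == 5
        for row in table.itertuples():
            if ":" in row.terms:
                assert "age_class" in row.terms and "adult_length" in row.terms

    def test_aic_tie_goes_to_fewer_coefficients(self):
        small = GlmFit(("a",), {"Intercept": 0.0, "a": 0.0}, {}, -10.0, 24.0, 50)
        big = GlmFit(("a", "b"), {"Intercept": 0.0, "a": 0.0, "b": 0.0}, {}, -9.0, 24.0, 50)
        assert min([big, small], key=_rank_key) is small

    def test_selection_recovers_single_true_effect(self):
        """With a log-odds ratio of 1.5 for the older class, the selected
        model contains the age-class term in the majority of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 254
            msw = rng.random(n) < 0.5
            data = pd.DataFrame(
                {
                    "age_class": np.where(msw, "MSW", "1SW"),
                    "sex": rng.choice(["F", "M"], n),
                    "smolt_length": rng.normal(13.7, 1.1, n),
                }
            )
            eta = -2.5 + 1.5 * msw
            data["response"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            best, _ = all_subsets_aic(data, ("age_class", "sex", "smolt_length"))
            hits += "age_class" in best.terms
        assert hits / n_rep > 0.5
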