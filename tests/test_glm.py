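"""Maximum-likelihood fitting: design building, IRLS, NB dispersion, BIC."""

import math

import numpy as np
import pandas as pd
import pytest

from prevratio import (ContingencyTable2x2, ModelSpec, RankDeficiencyError,
                       SubjectData, Term, ValidationError, bic, build_design,
                       crude_or, crude_pr, extract_effect, fit_glm, fit_model,
                       fit_negbin, table_to_subjects)
from prevratio.glm import _irls, family_loglik

LOG_FAMILIES = ("log_binomial", "log_poisson", "negative_log_binomial")


def _design_from_table(table):
    data = SubjectData(table_to_subjects(table))
    return build_design(data, ModelSpec("log_poisson"))


@pytest.fixture()
def age_frame(rng):
    n = 300
    df = pd.DataFrame({
        "outcome": rng.integers(0, 2, n),
        "exposure": rng.integers(0, 2, n),
        "age": rng.uniform(18, 56, n),
        "age_group": rng.choice(["<=25", "26-29", "30-34", ">=35"], n),
    })
    return SubjectData(df)


class TestBuildDesign:
    def test_four_level_factor_gives_three_dummies(self, age_frame):
        spec = ModelSpec("log_poisson",
                         (Term("age_group", "categorical", reference="<=25"),))
        y, X, names = build_design(age_frame, spec)
        assert names == ["intercept", "exposure", "age_group[26-29]",
                         "age_group[30-34]", "age_group[>=35]"]
        assert X.shape[1] == 5
        assert np.all(X[:, 0] == 1)

    def test_numeric_covariate_passthrough(self, age_frame):
        y, X, names = build_design(
            age_frame, ModelSpec("log_poisson", (Term("age"),)))
        assert names[-1] == "age"
        assert np.array_equal(X[:, -1], age_frame.frame["age"].to_numpy())

    def test_no_covariates_gives_two_columns(self, age_frame):
        y, X, names = build_design(age_frame, ModelSpec("log_poisson"))
        assert names == ["intercept", "exposure"]

    def test_unseen_level_named_in_error(self, age_frame):
        spec = ModelSpec("log_poisson",
                         (Term("age_group", "categorical", reference="<=25",
                               levels=("<=25", "26-29")),))
        with pytest.raises(ValidationError, match="30-34|>=35"):
            build_design(age_frame, spec)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            SubjectData(pd.DataFrame({"outcome": [0, 2], "exposure": [0, 1]}))


class TestSaturatedFits:
    @pytest.mark.parametrize("cells", [(10, 90, 5, 95), (40, 60, 25, 75),
                                       (300, 50, 200, 150)])
    def test_log_link_families_reproduce_crude_pr(self, cells):
        t = ContingencyTable2x2(*cells)
        y, X, names = _design_from_table(t)
        expected = (math.log(t.p2), math.log(t.p1 / t.p2))
        for fam in LOG_FAMILIES:
            f = fit_glm(y, X, fam, names=names)
            assert f.converged == "yes"
            assert f.beta == pytest.approx(expected, abs=1e-8), fam

    def test_logistic_reproduces_crude_or(self, simple_table):
        y, X, names = _design_from_table(simple_table)
        f = fit_glm(y, X, "logistic", names=names)
        assert math.exp(f.beta[1]) == pytest.approx(
            crude_or(simple_table).point, abs=1e-8)

    def test_cox_constant_time_is_bit_identical_alias(self, simple_table):
        y, X, names = _design_from_table(simple_table)
        fa = fit_glm(y, X, "cox_constant_time", names=names)
        fb = fit_glm(y, X, "log_poisson", names=names)
        assert np.array_equal(fa.beta, fb.beta)
        assert np.array_equal(fa.cov_model, fb.cov_model)
        assert fa.loglik == fb.loglik and fa.bic == fb.bic


class TestIRLS:
    def test_loglik_monotone_over_iteration_budgets(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(0, 1, n)])
        y = (rng.uniform(size=n) < np.exp(-2 + 0.5 * X[:, 1] + 0.3 * X[:, 2])
             ).astype(float)
        lls = [_irls("log_binomial", y, X, None, None, 1e-12, k)[1]
               for k in range(1, 12)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_gradient_small_at_convergence(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = (rng.uniform(size=n) < np.exp(-1.5 + 0.4 * X[:, 1])).astype(float)
        for fam in LOG_FAMILIES + ("logistic",):
            f = fit_glm(y, X, fam)
            assert f.converged == "yes"
            assert f.grad_norm <= max(1e-4, 1e-6 * n)

    def test_collinear_design_raises(self, rng):
        n = 50
        x = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), x, x])
        with pytest.raises(RankDeficiencyError):
            fit_glm(np.zeros(n) + (x > 2), X, "log_poisson")

    def test_high_prevalence_boundary_reported_not_raised(self, rng):
        # nearly saturated exposed cell: log-binomial pins at mu -> 1
        n = 4000
        e = (rng.uniform(size=n) < 0.3).astype(float)
        age = rng.uniform(18, 56, n)
        p = np.where(e == 1, 0.9997, 0.94)
        y = (rng.uniform(size=n) < p).astype(float)
        X = np.column_stack([np.ones(n), e, age])
        f = fit_glm(y, X, "log_binomial")
        assert f.converged in ("no_boundary", "no_maxiter")
        for fam in ("log_poisson", "negative_log_binomial"):
            assert fit_glm(y, X, fam).converged == "yes"


class TestNegativeBinomial:
    def test_collapses_to_poisson_on_binary_data(self, simple_table):
        y, X, names = _design_from_table(simple_table)
        nb = fit_negbin(y, X, names=names)
        po = fit_glm(y, X, "log_poisson", names=names)
        assert nb.alpha == 0.0
        assert nb.beta == pytest.approx(po.beta, abs=1e-6)
        assert nb.loglik == pytest.approx(po.loglik, abs=1e-8)

    def test_dispersion_recovery_from_overdispersed_counts(self):
        estimates = []
        for seed in range(3):
            rg = np.random.default_rng(seed)
            n = 20000
            X = np.column_stack([np.ones(n), rg.integers(0, 2, n)])
            mu = np.exp(0.5 + 0.7 * X[:, 1])
            y = rg.poisson(mu * rg.gamma(2.0, 0.5, size=n)).astype(float)
            estimates.append(fit_negbin(y, X).alpha)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)

    def test_model_se_exceeds_poisson_se_under_overdispersion(self, rng):
        n = 5000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        mu = np.exp(0.2 + 0.5 * X[:, 1])
        y = rng.poisson(mu * rng.gamma(1.0, 1.0, size=n)).astype(float)
        nb = fit_negbin(y, X)
        po = fit_glm(y, X, "log_poisson")
        assert nb.alpha > 0
        assert np.all(nb.se() >= po.se())

    def test_non_integer_outcome_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            fit_negbin(np.array([0.5, 1.0]), np.ones((2, 1)))


class TestInformationCriterion:
    def test_arithmetic_from_components(self):
        f = fit_glm(np.array([0., 1, 0, 1]),
                    np.column_stack([np.ones(4), [0., 0, 1, 1]]), "logistic")
        assert bic(f) == pytest.approx(-2 * f.loglik + 2 * math.log(4))
        # the textbook example: 2 params, loglik -100, n = 1000
        assert -2 * -100 + 2 * math.log(1000) == pytest.approx(213.8155, abs=1e-4)

    def test_nested_model_difference(self, rng):
        n = 600
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=n)])
        y = (rng.uniform(size=n) < np.exp(-1.5 + 0.3 * X[:, 1])).astype(float)
        small = fit_glm(y, X[:, :2], "log_poisson")
        big = fit_glm(y, X, "log_poisson")
        assert (bic(big) - bic(small)) == pytest.approx(
            -2 * (big.loglik - small.loglik) + math.log(n), abs=1e-8)

    def test_nb_preferred_on_overdispersed_counts(self, rng):
        n = 4000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        mu = np.exp(0.5 + 0.4 * X[:, 1])
        y = rng.poisson(mu * rng.gamma(1.25, 0.8, size=n)).astype(float)
        assert bic(fit_negbin(y, X)) < bic(fit_glm(y, X, "log_poisson"))

    def test_undefined_for_nonconverged_fit(self, rng):
        n = 2000
        e = (rng.uniform(size=n) < 0.3).astype(float)
        y = (rng.uniform(size=n) < np.where(e == 1, 0.9998, 0.92)).astype(float)
        X = np.column_stack([np.ones(n), e, rng.uniform(18, 56, n)])
        f = fit_glm(y, X, "log_binomial")
        if f.converged != "yes":
            assert math.isnan(bic(f))


class TestEffectExtraction:
    def test_null_coefficient_gives_unit_pr(self):
        y = np.array([0., 1, 0, 1])
        X = np.column_stack([np.ones(4), [0., 0, 1, 1]])
        f = fit_glm(y, X, "log_poisson", names=["intercept", "exposure"])
        e = extract_effect(f, "exposure")
        assert e.point == pytest.approx(1.0, abs=1e-8)
        assert e.measure == "PR"

    def test_measure_is_or_for_logistic(self, simple_table):
        y, X, names = _design_from_table(simple_table)
        f = fit_glm(y, X, "logistic", names=names)
        assert extract_effect(f, "exposure").measure == "OR"

    def test_unknown_term_rejected(self, simple_table):
        y, X, names = _design_from_table(simple_table)
        f = fit_glm(y, X, "log_poisson", names=names)
        with pytest.raises(ValidationError):
            extract_effect(f, "not_a_term")

    def test_fit_model_convenience_matches_manual_path(self, simple_table):
        data = SubjectData(table_to_subjects(simple_table))
        spec = ModelSpec("negative_log_binomial")
        f1 = fit_model(data, spec)
        y, X, names = build_design(data, spec)
        f2 = fit_glm(y, X, "negative_log_binomial", names=names)
        assert f1.beta == pytest.approx(f2.beta, abs=0)
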