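"""Collinearity filtering, model selection, GLM fits and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from aliendrivers.models import (
    filter_collinear,
    fit_glm,
    forward_select,
    influence_diagnostics,
    kfold_cv,
    overdispersion_test,
    standardize,
)


def vif_oracle(X: np.ndarray, j: int) -> float:
    """Independent normal-equations solve of the auxiliary regression."""
    y = X[:, j]
    Z = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    r2 = 1 - np.sum((y - Z @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
    return 1.0 / (1.0 - r2)


class TestVif:
    def test_orthogonal_predictors_untouched(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        kept, report = filter_collinear(X, 10.0)
        assert list(kept.columns) == ["a", "b"]
        assert report.removed == []
        assert all(v == pytest.approx(1.0) for v in report.vif.values())

    def test_exact_duplicate_removed_first(self, rng):
        base = rng.normal(size=30)
        X = pd.DataFrame({"a": base, "b": base.copy(), "c": rng.normal(size=30)})
        kept, report = filter_collinear(X, 10.0)
        assert len(report.removed) == 1
        assert report.removed[0][0] == "a"  # alphabetical tie-break
        assert np.isinf(report.removed[0][1])
        assert "b" in kept.columns and "c" in kept.columns

    def test_vif_matches_normal_equations_oracle(self, rng):
        # known correlation structure
        z = rng.normal(size=200)
        X = pd.DataFrame(
            {
                "p1": z + 0.3 * rng.normal(size=200),
                "p2": z + 0.3 * rng.normal(size=200),
                "p3": rng.normal(size=200),
            }
        )
        _, report = filter_collinear(X, threshold=1e9)
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            assert report.vif[name] == pytest.approx(vif_oracle(arr, j), rel=1e-8)

    def test_column_order_irrelevant(self, rng):
        z = rng.normal(size=80)
        cols = {
            "a": z + 0.05 * rng.normal(size=80),
            "b": z + 0.05 * rng.normal(size=80),
            "c": rng.normal(size=80),
            "d": rng.normal(size=80),
        }
        X1 = pd.DataFrame(cols)
        X2 = X1[["d", "b", "a", "c"]]
        kept1, r1 = filter_collinear(X1, 10.0)
        kept2, r2 = filter_collinear(X2, 10.0)
        assert set(kept1.columns) == set(kept2.columns)
        assert [n for n, _ in r1.removed] == [n for n, _ in r2.removed]


class TestGlmFit:
    def test_intercept_only_nb_recovers_mean(self, rng):
        y = rng.negative_binomial(2, 0.1, size=200)
        fit = fit_glm(y, pd.DataFrame(index=range(200)))
        assert np.exp(fit.coefficients.loc["intercept", "estimate"]) == pytest.approx(
            y.mean(), rel=1e-6
        )

    def test_equidispersed_limit_matches_poisson(self, rng):
        x = rng.normal(size=300)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        X = pd.DataFrame({"x": x})
        nb = fit_glm(y, X, family="negative_binomial")
        po = fit_glm(y, X, family="poisson")
        assert np.allclose(
            nb.coefficients["estimate"], po.coefficients["estimate"], atol=1e-4
        )

    def test_negative_response_under_nb_directs_to_gaussian(self):
        y = np.array([-3.0, 1.0, 2.0, 4.0])
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="gaussian"):
            fit_glm(y, X, family="negative_binomial")
        fit = fit_glm(y, X, family="gaussian")
        assert fit.converged

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            fit_glm(np.ones(3), X)

    def test_parameter_recovery_smoke(self, rng):
        # fuller 200-seed sweep lives in the acceptance suite
        beta = np.array([1.5, 0.4, -0.3])
        hits = 0
        for _ in range(20):
            X = rng.normal(size=(300, 2))
            mu = np.exp(beta[0] + X @ beta[1:])
            y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
            fit = fit_glm(y, pd.DataFrame(X, columns=["a", "b"]))
            est = fit.coefficients["estimate"].to_numpy()
            se = fit.coefficients["std_error"].to_numpy()
            hits += np.all(np.abs(est - beta) < 2 * se)
        assert hits >= 14


class TestForwardSelection:
    def test_single_informative_candidate_selected(self, rng):
        x = rng.normal(size=200)
        y = rng.poisson(np.exp(1.0 + 0.8 * x))
        trace = forward_select(y, pd.DataFrame({"x": x}), family="poisson")
        assert trace.final_predictors == ["x"]

    def test_criterion_non_increasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
        y = rng.poisson(np.exp(1.0 + 0.6 * X["a"] + 0.4 * X["c"]))
        trace = forward_select(y, X, family="poisson")
        values = [v for _, v in trace.steps]
        assert values == sorted(values, reverse=True)

    def test_noise_response_selects_little(self, rng):
        # forward AICc admits the occasional spurious candidate (the best of
        # ten noise predictors clears the ~2-unit AIC hurdle fairly often);
        # the selected model must stay small, far below the candidate count
        sizes = []
        for _ in range(40):
            X = pd.DataFrame(rng.normal(size=(200, 10)), columns=list("abcdefghij"))
            y = rng.poisson(np.exp(1.0 + np.zeros(200)))
            trace = forward_select(y, X, family="poisson")
            sizes.append(len(trace.final_predictors))
        assert np.median(sizes) <= 2
        assert max(sizes) <= 5

    def test_strong_effect_always_found(self, rng):
        found = 0
        for _ in range(40):
            X = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
            y = rng.poisson(np.exp(1.0 + 1.0 * X["c"]))
            trace = forward_select(y, X, family="poisson")
            found += "c" in trace.final_predictors
        assert found >= 38

    def test_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = rng.poisson(np.exp(1.0 + 0.5 * X["b"]))
        t1 = forward_select(y, X, family="poisson")
        t2 = forward_select(y, X, family="poisson")
        assert t1.final_predictors == t2.final_predictors
        assert t1.steps == t2.steps


class TestOverdispersion:
    def test_statistic_non_negative(self, rng):
        x = rng.normal(size=100)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        disp, p, _ = overdispersion_test(y, pd.DataFrame({"x": x}))
        assert disp >= 0 and 0 <= p <= 1

    def test_type_i_rate_controlled(self, rng):
        flags = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=200)
            y = rng.poisson(np.exp(1.0 + 0.3 * x))
            _, _, flag = overdispersion_test(y, pd.DataFrame({"x": x}))
            flags += flag
        assert 0.02 <= flags / reps <= 0.09

    def test_nb_data_detected(self, rng):
        flags = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(size=200)
            mu = np.exp(1.0 + 0.3 * x)
            y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
            _, _, flag = overdispersion_test(y, pd.DataFrame({"x": x}))
            flags += flag
        assert flags >= 0.95 * reps


class TestKfoldCv:
    def _data(self, rng, n=120):
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.poisson(np.exp(1.0 + 0.7 * X["x"]))
        return np.asarray(y), X

    def test_loo_edge_case(self, rng):
        y, X = self._data(rng, n=12)
        cv = kfold_cv(y, X, family="poisson", k=12, seed=0)
        assert cv.k == 12 and len(cv.per_fold_deviance) == 12

    def test_same_seed_same_folds(self, rng):
        y, X = self._data(rng)
        a = kfold_cv(y, X, family="poisson", k=5, seed=7)
        b = kfold_cv(y, X, family="poisson", k=5, seed=7)
        assert a.per_fold_deviance == b.per_fold_deviance

    def test_true_model_beats_intercept_only(self, rng):
        wins = 0
        for seed in range(30):
            y, X = self._data(rng)
            full = kfold_cv(y, X, family="poisson", k=5, seed=seed)
            null = kfold_cv(
                y, pd.DataFrame(index=X.index), family="poisson", k=5, seed=seed
            )
            wins += full.mean_deviance < null.mean_deviance
        assert wins >= 27


class TestInfluence:
    def test_balanced_design_equal_leverage(self):
        # replicated +-1 design: every point identical leverage p/n
        X = pd.DataFrame({"x": [1.0, -1.0] * 10})
        y = np.exp(1.0 + 0.2 * X["x"].to_numpy())
        fit = fit_glm(np.round(y), X, family="poisson")
        diag = influence_diagnostics(fit, X)
        assert np.allclose(diag["leverage"], 2 / 20, atol=1e-8)

    def test_leverage_sums_to_parameter_count(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.poisson(np.exp(1.0 + 0.4 * X["a"]))
        fit = fit_glm(y, X, family="poisson")
        diag = influence_diagnostics(fit, X)
        assert diag["leverage"].sum() == pytest.approx(4.0, abs=1e-8)

    def test_gross_outlier_ranked_most_influential(self, rng):
        hits = 0
        for _ in range(50):
            X = pd.DataFrame({"x": rng.normal(size=60)}, index=range(60))
            y = rng.poisson(np.exp(2.0 + 0.3 * X["x"].to_numpy())).astype(float)
            y[17] = y.max() * 8 + 50  # inject
            fit = fit_glm(y.round(), X, family="poisson")
            diag = influence_diagnostics(fit, X)
            hits += diag.loc[diag["influence"].idxmax(), "country"] == 17
        assert hits >= 45


class TestSignRecovery:
    def test_planted_driver_signs_recovered(self):
        """With effects planted on six drivers (positive monitoring,
        density, sustainability, tourism and growth; negative culture
        score), the fitted NB coefficients carry the planted sign in at
        least 90% of 200 simulated studies."""
        from aliendrivers.simulate import (
            SynthConfig,
            generate_predictors,
            generate_richness,
            standardize as z,
        )

        base = SynthConfig(seed=0, n_countries=100)
        names = list(base.true_beta)
        signs = np.sign([base.true_beta[n] for n in names])
        hits = np.zeros(len(names))
        for seed in range(200):
            cfg = SynthConfig(seed=seed, n_countries=100)
            table = generate_predictors(cfg)
            y = generate_richness(
                table, cfg.true_beta, cfg.nb_dispersion, seed + 10**6,
                intercept=cfg.intercept,
            )
            fit = fit_glm(y, z(table.data[names]))
            est = fit.coefficients.loc[names, "estimate"].to_numpy()
            hits += np.sign(est) == signs
        assert np.all(hits >= 0.90 * 200)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        X = pd.DataFrame(rng.normal(3.0, 5.0, size=(40, 3)), columns=list("abc"))
        Z = standardize(X)
        assert np.allclose(Z.mean(), 0.0, atol=1e-12)
        assert np.allclose(Z.std(ddof=0), 1.0, atol=1e-12)
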