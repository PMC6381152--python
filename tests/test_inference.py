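"""Posterior attribution, permutation inference, and schema-strength statistics."""

import numpy as np
import pandas as pd
import pytest

from circschema import (
    MODELS,
    CellParams,
    MixtureParams,
    compare_independent_correlations,
    exclude_low_performers,
    fit_model,
    mean_component_probability,
    pearson_correlation,
    permutation_test,
    responsibilities,
    schema_strength,
    simulate_cell_trials,
    standardized_regression,
)
from circschema.circular import wrap_circle
from circschema.models import FitResult, information_criteria


def _fit_result(model_id, kappa, p_guess, p_schema=None, n=100):
    params = MixtureParams(kappa=kappa, p_guess=p_guess, p_schema=p_schema)
    model = MODELS[model_id]
    aic, bic = information_criteria(-1.0, model.n_free_params, n)
    return FitResult(model=model, params=params, log_likelihood=-1.0, n_trials=n, aic=aic, bic=bic)


@pytest.fixture(scope="module")
def m4_trials():
    return simulate_cell_trials(16, 100, CellParams(0.55, 0.30, 0.15, 15.0), seed=5)


class TestResponsibilities:
    def test_rows_normalized(self, m4_trials):
        fit = fit_model(MODELS["M4"], m4_trials, n_starts=6, seed=0)
        r = responsibilities(fit, m4_trials)
        assert list(r.columns) == ["target", "schema", "guess"]
        assert np.all(r.to_numpy() >= 0)
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_pure_target(self, m4_trials):
        fit = _fit_result("M4", 15.0, 0.0, 0.0)
        r = responsibilities(fit, m4_trials)
        assert np.allclose(r["target"], 1.0)

    def test_symmetric_response_equal_split(self):
        """Response equidistant from target and old schema mean, equal weights."""
        df = simulate_cell_trials(1, 1, CellParams(1.0, 0.0, 0.0, 10.0), seed=0)
        df["target"] = 90.0
        df["schema_mean_original"] = 180.0
        df["response"] = 135.0  # midway
        fit = _fit_result("M4", 8.0, 0.0, 0.5)
        r = responsibilities(fit, df)
        assert r["target"].iloc[0] == pytest.approx(r["schema"].iloc[0])

    def test_mean_responsibility_equals_fitted_weight(self, m4_trials):
        """EM fixed point: mean component responsibility = mixing weight at the MLE."""
        fit = fit_model(MODELS["M4"], m4_trials, seed=0)
        r = responsibilities(fit, m4_trials)
        assert mean_component_probability(r, "schema") == pytest.approx(fit.p_schema, abs=1e-3)
        assert mean_component_probability(r, "guess") == pytest.approx(fit.p_guess, abs=1e-3)
        assert mean_component_probability(r, "target") == pytest.approx(fit.p_target, abs=1e-3)

    def test_unknown_component_rejected(self, m4_trials):
        fit = fit_model(MODELS["M3"], m4_trials, n_starts=4, seed=0)
        r = responsibilities(fit, m4_trials)
        with pytest.raises(KeyError):
            mean_component_probability(r, "schema")


class TestPermutationTest:
    def test_exchangeable_duplicate_gives_p_one(self, m4_trials):
        """Group B an exact relabelled copy of A: zero difference, p = 1."""
        b = m4_trials.copy()
        b["participant_id"] = "x" + b["participant_id"]
        res = permutation_test(m4_trials, b, "M4", n_iter=100, seed=0, n_starts=4)
        assert res.observed_diff == pytest.approx(0.0, abs=1e-9)
        assert res.p_two_tailed == 1.0

    def test_group_label_swap_invariance(self, m4_trials):
        """Two-tailed p is invariant to which group is called A."""
        other = simulate_cell_trials(16, 100, CellParams(0.75, 0.10, 0.15, 15.0), seed=9)
        other["participant_id"] = "y" + other["participant_id"]
        r1 = permutation_test(m4_trials, other, "M4", n_iter=200, seed=3, n_starts=4)
        r2 = permutation_test(other, m4_trials, "M4", n_iter=200, seed=3, n_starts=4)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed, abs=0.05)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff, abs=1e-6)

    def test_detects_large_group_difference(self):
        a = simulate_cell_trials(16, 56, CellParams(0.41, 0.49, 0.10, 15.0), seed=21)
        b = simulate_cell_trials(16, 56, CellParams(0.58, 0.32, 0.10, 15.0), seed=22)
        b["participant_id"] = "z" + b["participant_id"]
        res = permutation_test(a, b, "M4", n_iter=300, seed=1, n_starts=4)
        assert res.observed_diff > 0.05
        assert res.p_two_tailed < 0.05

    def test_requires_disjoint_participants(self, m4_trials):
        with pytest.raises(ValueError, match="both groups"):
            permutation_test(m4_trials, m4_trials, "M4", n_iter=10, seed=0)

    def test_requires_schema_model(self, m4_trials):
        b = m4_trials.copy()
        b["participant_id"] = "x" + b["participant_id"]
        with pytest.raises(ValueError, match="schema"):
            permutation_test(m4_trials, b, "M3", n_iter=10, seed=0)


class TestSchemaStrength:
    def _is_frame(self, inside_err, outside_err):
        n_in, n_out = len(inside_err), len(outside_err)
        return pd.DataFrame(
            {
                "participant_id": "p0",
                "group": "no_consolidation",
                "phase": "IS",
                "block": 0,
                "category": "animals",
                "category_role": "consistent",
                "quadrant": ["inside"] * n_in + ["outside"] * n_out,
                "is_critical": False,
                "target": 100.0,
                "response": [100.0 + e for e in inside_err] + [100.0 + e for e in outside_err],
                "schema_mean_current": 100.0,
                "schema_mean_original": 100.0,
            }
        )

    def test_difference_of_means(self):
        df = self._is_frame([10, 10, -10], [30, -30])
        out = schema_strength(df)
        assert out["strength"].iloc[0] == pytest.approx(30.0 - 10.0)

    def test_rotation_invariance(self):
        df = self._is_frame([5, -15, 10], [40, -50])
        base = schema_strength(df)["strength"].iloc[0]
        rot = df.copy()
        for col in ("target", "response", "schema_mean_current", "schema_mean_original"):
            rot[col] = wrap_circle(rot[col].to_numpy(float) + 211.0)
        assert schema_strength(rot)["strength"].iloc[0] == pytest.approx(base)

    def test_missing_cell_rejected(self):
        df = self._is_frame([10, 10], [])
        with pytest.raises(ValueError, match="inside and outside"):
            schema_strength(df)

    def test_positive_under_simulator_defaults(self, small_experiment):
        """A schema component in IS makes outside errors exceed inside errors."""
        out = schema_strength(small_experiment)
        assert out["strength"].mean() > 0


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_orthogonal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_correlation(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_negative_with_noise(self, rng):
        x = rng.normal(size=500)
        y = -x + rng.normal(scale=0.5, size=500)
        assert pearson_correlation(x, y) < -0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_equal_correlations_give_zero_z(self):
        res = compare_independent_correlations(0.3, 20, 0.3, 50)
        assert res.z == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_antisymmetric_in_swap(self):
        a = compare_independent_correlations(0.6, 30, 0.2, 40)
        b = compare_independent_correlations(0.2, 40, 0.6, 30)
        assert a.z == pytest.approx(-b.z)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            compare_independent_correlations(1.0, 30, 0.2, 30)
        with pytest.raises(ValueError):
            compare_independent_correlations(0.5, 3, 0.2, 30)


class TestStandardizedRegression:
    def test_identity_single_predictor(self):
        y = np.arange(20.0)
        res = standardized_regression(y, {"x": y.copy()})
        assert res.betas["x"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_null_predictors_small_r2(self, rng):
        y = rng.normal(size=2000)
        x = pd.DataFrame({"a": rng.normal(size=2000), "b": rng.normal(size=2000)})
        res = standardized_regression(y, x)
        assert res.r_squared < 0.01
        assert res.f_pvalue > 0.01

    def test_recovers_known_standardized_effects(self, rng):
        """Monte-Carlo: betas 0.45/0.35 with orthogonal predictors, n=32."""
        b1, b2, n = 0.45, 0.35, 32
        resid_sd = np.sqrt(1.0 - b1**2 - b2**2)
        est = np.zeros((200, 2))
        for i in range(200):
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            y = b1 * x1 + b2 * x2 + resid_sd * rng.normal(size=n)
            res = standardized_regression(y, {"x1": x1, "x2": x2})
            est[i] = res.betas["x1"], res.betas["x2"]
        se = est.std(axis=0) / np.sqrt(len(est))
        assert abs(est[:, 0].mean() - b1) < 4 * se[0] + 0.01
        assert abs(est[:, 1].mean() - b2) < 4 * se[1] + 0.01

    def test_rank_deficiency_rejected(self):
        y = np.arange(10.0)
        x = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(ValueError):
            standardized_regression(y, x)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n >"):
            standardized_regression([1.0, 2.0, 3.0], {"a": [1, 2, 3], "b": [3, 1, 2]})


def test_exclude_low_performers(small_experiment):
    """A participant responding at random across FT is excluded by the 2-SD rule."""
    df = small_experiment.copy()
    bad = df["participant_id"] == "nc00"
    ft_bad = bad & (df["phase"] == "FT")
    rng = np.random.default_rng(0)
    df.loc[ft_bad, "response"] = rng.uniform(0, 360, size=int(ft_bad.sum()))
    kept = exclude_low_performers(df)
    assert "nc00" not in set(kept["participant_id"])
    assert kept["participant_id"].nunique() == df["participant_id"].nunique() - 1
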