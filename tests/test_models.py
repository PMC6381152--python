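"""Mixture-model likelihoods, fitting, and AIC/BIC comparison."""

import numpy as np
import pytest

from circschema import (
    MODELS,
    CellParams,
    MixtureParams,
    compare_models,
    fit_model,
    fit_model_em,
    information_criteria,
    simulate_cell_trials,
    trial_loglik,
)
from circschema.circular import wrap_circle


@pytest.fixture(scope="module")
def m4_trials():
    return simulate_cell_trials(8, 200, CellParams(0.60, 0.30, 0.10, 15.0), seed=42)


class TestTrialLoglik:
    def test_pure_guessing(self, m4_trials):
        """With p_guess = 1 every trial has the uniform log density."""
        ll = trial_loglik(MODELS["M1"], MixtureParams(kappa=5.0, p_guess=1.0), m4_trials)
        assert np.allclose(ll, np.log(1.0 / 360.0))

    def test_pure_target_at_zero_error(self, m4_trials):
        from circschema import vonmises_pdf

        df = m4_trials.copy()
        df["response"] = df["target"]
        ll = trial_loglik(MODELS["M1"], MixtureParams(kappa=12.0, p_guess=0.0), df)
        assert np.allclose(ll, np.log(vonmises_pdf(0.0, 0.0, 12.0)))

    def test_m4_with_zero_schema_equals_m3(self, m4_trials):
        p3 = MixtureParams(kappa=9.0, p_guess=0.2)
        p4 = MixtureParams(kappa=9.0, p_guess=0.2, p_schema=0.0)
        ll3 = trial_loglik(MODELS["M3"], p3, m4_trials)
        ll4 = trial_loglik(MODELS["M4"], p4, m4_trials)
        assert np.allclose(ll3, ll4)

    def test_missing_response_rejected(self, m4_trials):
        df = m4_trials.copy()
        df.loc[df.index[0], "response"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            trial_loglik(MODELS["M3"], MixtureParams(kappa=5.0, p_guess=0.5), df)

    def test_weights_outside_simplex_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams(kappa=5.0, p_guess=0.7, p_schema=0.5)
        with pytest.raises(ValueError):
            MixtureParams(kappa=5.0, p_guess=-0.1)


class TestInformationCriteria:
    def test_arithmetic(self):
        aic, bic = information_criteria(-100.0, 2, 50)
        assert aic == pytest.approx(204.0)
        assert bic == pytest.approx(2 * np.log(50) + 200.0)

    def test_bic_penalty_gap(self):
        """At equal logL and n=1000, one extra parameter costs ln(1000) BIC."""
        _, bic2 = information_criteria(-500.0, 2, 1000)
        _, bic3 = information_criteria(-500.0, 3, 1000)
        assert bic3 - bic2 == pytest.approx(np.log(1000.0))

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 2, 0)


def _grid_oracle_logl(trials, model, weight_step=0.01, n_kappa=50):
    """Exhaustive grid search over the weight simplex x log-spaced kappas."""
    best = -np.inf
    kappas = np.geomspace(0.5, 100.0, n_kappa)
    ps_grid = np.arange(0.0, 1.0 + 1e-9, weight_step)
    for kappa in kappas:
        for p_schema in ps_grid if model.has_schema else [None]:
            rem = 1.0 if p_schema is None else 1.0 - p_schema
            for p_guess in np.arange(0.0, rem + 1e-9, weight_step):
                params = MixtureParams(
                    kappa=kappa, p_guess=min(p_guess, rem), p_schema=p_schema
                )
                ll = trial_loglik(model, params, trials).sum()
                if ll > best:
                    best = ll
    return best


class TestFitModel:
    def test_recovers_generative_parameters(self):
        """Pooled M4 fit on 3584 simulated trials recovers weights and kappa."""
        trials = simulate_cell_trials(64, 56, CellParams(0.60, 0.30, 0.10, 15.0), seed=7)
        fit = fit_model(MODELS["M4"], trials, seed=0)
        assert fit.p_schema == pytest.approx(0.30, abs=0.03)
        assert fit.p_guess == pytest.approx(0.10, abs=0.03)
        assert fit.p_target == pytest.approx(0.60, abs=0.03)
        assert fit.kappa == pytest.approx(15.0, rel=0.15)

    def test_nested_truth_gives_near_zero_schema(self):
        """Data with no schema component: M4's schema weight fits to ~0."""
        estimates = []
        for rep in range(20):
            trials = simulate_cell_trials(
                4, 500, CellParams(0.80, 0.0, 0.20, 10.0), seed=100 + rep
            )
            fit = fit_model(MODELS["M4"], trials, n_starts=6, seed=rep)
            estimates.append(fit.p_schema)
        assert np.mean(estimates) < 0.03

    def test_agrees_with_grid_oracle(self):
        """Optimizer's optimum is at least as good as an exhaustive grid search."""
        trials = simulate_cell_trials(1, 200, CellParams(0.55, 0.30, 0.15, 12.0), seed=3)
        model = MODELS["M4"]
        fit = fit_model(model, trials, seed=0)
        oracle = _grid_oracle_logl(trials, model)
        assert fit.log_likelihood >= oracle - 1e-4

    def test_em_reaches_same_optimum(self, m4_trials):
        """The EM cross-check converges to the direct optimizer's solution."""
        direct = fit_model(MODELS["M4"], m4_trials, seed=0)
        em = fit_model_em(MODELS["M4"], m4_trials, tol=1e-12)
        assert em.log_likelihood == pytest.approx(direct.log_likelihood, abs=1e-3)
        assert em.p_schema == pytest.approx(direct.p_schema, abs=1e-3)
        assert em.kappa == pytest.approx(direct.kappa, rel=1e-2)

    def test_degenerate_single_trial_flagged(self):
        trials = simulate_cell_trials(1, 1, CellParams(1.0, 0.0, 0.0, 50.0), seed=1)
        trials["response"] = trials["target"]
        with pytest.warns(RuntimeWarning, match="guard"):
            fit = fit_model(MODELS["M1"], trials, n_starts=4, seed=0)
        assert fit.degenerate
        assert fit.p_guess < 0.05

    def test_missing_responses_excluded(self, m4_trials):
        df = m4_trials.copy()
        df.loc[df.index[:100], "response"] = np.nan
        fit = fit_model(MODELS["M4"], df, n_starts=4, seed=0)
        assert fit.n_trials == len(df) - 100

    def test_no_trials_rejected(self, m4_trials):
        df = m4_trials.iloc[:0]
        with pytest.raises(ValueError):
            fit_model(MODELS["M4"], df)


class TestInvariants:
    def test_nesting(self, m4_trials):
        """A richer model never fits worse than the model nested inside it."""
        cmp = compare_models(m4_trials, ["M3", "M4", "M5"], n_starts=6, seed=0)
        assert cmp.fits["M4"].log_likelihood >= cmp.fits["M3"].log_likelihood - 1e-6
        assert cmp.fits["M5"].log_likelihood >= cmp.fits["M3"].log_likelihood - 1e-6

    def test_rotation_invariance(self, m4_trials):
        """Rigidly rotating all angles leaves fits and deltas unchanged."""
        fit = fit_model(MODELS["M4"], m4_trials, n_starts=6, seed=0)
        rotated = m4_trials.copy()
        for col in ("target", "response", "schema_mean_current", "schema_mean_original"):
            rotated[col] = wrap_circle(rotated[col].to_numpy() + 123.4)
        fit_rot = fit_model(MODELS["M4"], rotated, n_starts=6, seed=0)
        assert fit_rot.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-5)
        assert fit_rot.p_schema == pytest.approx(fit.p_schema, abs=1e-5)
        assert fit_rot.kappa == pytest.approx(fit.kappa, rel=1e-5)

    def test_duplicated_data_doubles_loglik(self, m4_trials):
        import pandas as pd

        cmp1 = compare_models(m4_trials, ["M3", "M4"], n_starts=6, seed=0)
        doubled = pd.concat([m4_trials, m4_trials], ignore_index=True)
        cmp2 = compare_models(doubled, ["M3", "M4"], n_starts=6, seed=0)
        for mid in ("M3", "M4"):
            assert cmp2.fits[mid].log_likelihood == pytest.approx(
                2 * cmp1.fits[mid].log_likelihood, rel=1e-6
            )
        # AIC delta = -2 + 2*(logL4 - logL3); doubling the data doubles the
        # log-likelihood gap but not the parameter penalty
        assert cmp2.aic_delta("M3", "M4") == pytest.approx(
            2 * cmp1.aic_delta("M3", "M4") + 2.0, abs=0.1
        )
        assert cmp2.preferred == cmp1.preferred


class TestCompareModels:
    def test_preferred_attains_minimum(self, m4_trials):
        cmp = compare_models(m4_trials, ["M3", "M4", "M5"], n_starts=6, seed=0)
        assert cmp.preferred == min(cmp.fits, key=lambda m: cmp.fits[m].aic)
        deltas = cmp.deltas_vs_preferred
        assert deltas[cmp.preferred] == (0.0, 0.0)
        assert all(d[0] >= 0 for d in deltas.values())

    def test_needs_two_models(self, m4_trials):
        with pytest.raises(ValueError):
            compare_models(m4_trials, ["M4"])
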