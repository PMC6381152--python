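"""Trial-level component attribution, permutation inference and schema-strength analyses.

Given a fitted mixture model, each response can be attributed post hoc to the
component most likely to have generated it: the *responsibility* of component
``c`` on a trial is ``w_c f_c(response) / sum_k w_k f_k(response)`` at the
fitted parameters.  The group-level statistic of interest is the mean
old-schema responsibility; at an interior maximum-likelihood solution it
coincides with the fitted old-schema mixing weight (the EM fixed point).

Group inference follows the pooled-fit permutation scheme: participants are
randomly reassigned to two groups of the original sizes, the mixture model is
refitted to each permuted group's pooled trials, and the two-tailed p-value
is the proportion of permutations whose absolute group difference reaches the
observed one.  The permutation refits run through a vectorised EM engine (all
permutations in parallel) warm-started from the all-data pooled fit.

Schema strength is an individual-difference measure from the Initial Study
phase: mean absolute error on outside-quadrant trials minus inside-quadrant
trials, per participant and category.  Its relation to later old-schema
responding is quantified with Pearson correlations, a Fisher r-to-z
comparison of two independent correlations, and a standardized two-predictor
regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import i0e

from .circular import abs_error
from .models import (
    MODELS,
    FitResult,
    MixtureParams,
    ModelSpec,
    _component_logliks,
    _prepare,
    fit_model,
)

__all__ = [
    "responsibilities",
    "mean_component_probability",
    "PermutationResult",
    "permutation_test",
    "schema_strength",
    "pearson_correlation",
    "CorrelationComparison",
    "compare_independent_correlations",
    "RegressionResult",
    "standardized_regression",
    "exclude_low_performers",
]


# ---------------------------------------------------------------------------
# responsibilities
# ---------------------------------------------------------------------------

def responsibilities(fit: FitResult, trials: pd.DataFrame) -> pd.DataFrame:
    """Posterior probability of each mixture component for every trial.

    Columns are the model's components (``target``, ``schema`` for the
    three-component models, ``guess``); each row is non-negative and sums
    to 1.  Trials with missing responses are rejected.
    """
    model = fit.model
    resp = trials["response"].to_numpy(float)
    if not np.all(np.isfinite(resp)):
        raise ValueError("responsibilities: trials with missing responses present")
    cos_t, cos_s = _prepare(model, trials, allow_missing=False)
    comp = _component_logliks(cos_t, cos_s, fit.params)
    ll = np.logaddexp.reduce(comp, axis=0)
    r = np.exp(comp - ll)
    return pd.DataFrame(r.T, columns=list(model.components), index=trials.index)


def mean_component_probability(resp_table: pd.DataFrame, component: str) -> float:
    """Arithmetic mean of one component's responsibility column."""
    if len(resp_table) == 0:
        raise ValueError("empty responsibility table")
    if component not in resp_table.columns:
        raise KeyError(
            f"unknown component {component!r}; available: {list(resp_table.columns)}"
        )
    return float(resp_table[component].mean())


# ---------------------------------------------------------------------------
# permutation test on pooled fits
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Two-tailed participant-level permutation test of a group difference.

    ``p_two_tailed`` is the plain proportion of permutations whose absolute
    null difference is at least the observed one (ties count as exceeding,
    the conservative choice); ``p_add_one`` is the Phipson-Smyth add-one
    version, reported for the p = 0 edge case.
    """

    observed_diff: float
    null_diffs: np.ndarray
    p_two_tailed: float
    p_add_one: float
    n_iter: int
    seed: Optional[int]
    observed_a: float
    observed_b: float

    def __repr__(self):  # keep the array out of the default repr
        return (
            f"PermutationResult(observed_diff={self.observed_diff:.4f}, "
            f"p_two_tailed={self.p_two_tailed:.4f}, n_iter={self.n_iter})"
        )


def _em_engine(
    cos_t,
    cos_s,
    mask,
    init: MixtureParams,
    max_iter: int = 400,
    tol: float = 1e-6,
    weight_subiters: int = 3,
):
    """Run EM to convergence for every permutation mask in parallel.

    ``mask``: (P, n) boolean/0-1 trial inclusion per permutation.  Returns
    (weights, kappa) per permutation; the schema weight equals the mean
    schema responsibility at convergence (EM fixed point).

    Engineered for the permutation null: the expensive von Mises kernels
    (one exp per trial x permutation) are evaluated in float32 and reused
    across a few weight-only sub-iterations per kappa update; permutations
    whose parameters have stopped moving (max change < ``tol``) drop out of
    the active set.  Parameters themselves are kept in float64.
    """
    from .models import _a_inv  # local import to avoid a cycle at module load

    has_schema = cos_s is not None
    n_comp = 3 if has_schema else 2
    p_total = mask.shape[0]
    ct = (np.asarray(cos_t) - 1.0).astype(np.float32)
    cs_ = (np.asarray(cos_s) - 1.0).astype(np.float32) if has_schema else None
    m32 = np.asarray(mask, dtype=np.float32)

    if has_schema:
        w0 = np.array([init.p_target, max(init.p_schema or 0.0, 1e-4), init.p_guess])
    else:
        w0 = np.array([init.p_target, init.p_guess])
    w0 = w0 / w0.sum()

    out_w = np.empty((p_total, n_comp))
    out_k = np.empty(p_total)
    idx = np.arange(p_total)
    w = np.tile(w0, (p_total, 1))
    k = np.full(p_total, np.clip(init.kappa, 1e-3, 199.0))
    m_act = m32
    n_act = m_act.sum(axis=1, dtype=np.float64)
    two_pi = 2.0 * np.pi

    for _ in range(max_iter):
        w_outer = w.copy()
        b0 = 1.0 / (two_pi * i0e(k))
        ft = np.exp(k[:, None].astype(np.float32) * ct)
        fs = np.exp(k[:, None].astype(np.float32) * cs_) if has_schema else None
        for _sub in range(weight_subiters):
            st = (w[:, 0] * b0)[:, None].astype(np.float32) * ft
            sg = (w[:, -1] / two_pi).astype(np.float32)
            if has_schema:
                ss = (w[:, 1] * b0)[:, None].astype(np.float32) * fs
                tot = st + ss + sg[:, None]
            else:
                ss = None
                tot = st + sg[:, None]
            inv = m_act / tot
            n_t = np.einsum("pn,pn->p", st, inv, dtype=np.float64)
            if has_schema:
                n_s = np.einsum("pn,pn->p", ss, inv, dtype=np.float64)
                w = np.stack([n_t, n_s, n_act - n_t - n_s], axis=1) / n_act[:, None]
            else:
                w = np.stack([n_t, n_act - n_t], axis=1) / n_act[:, None]
            w = np.clip(w, 1e-10, 1.0)
            w /= w.sum(axis=1, keepdims=True)
        # kappa update from the von Mises resultant at current responsibilities
        num = np.einsum("pn,pn,n->p", st, inv, ct, dtype=np.float64) + n_t
        vm_mass = n_t
        if has_schema:
            num = num + np.einsum("pn,pn,n->p", ss, inv, cs_, dtype=np.float64) + n_s
            vm_mass = n_t + n_s
        resultant = np.clip(num / np.maximum(vm_mass, 1e-300), 0.0, 1.0)
        k_new = _a_inv(resultant)
        delta_k = np.abs(k_new - k) / (k + 1.0)
        delta_w = np.abs(w - w_outer).max(axis=1)
        k = k_new
        done = (delta_k < tol) & (delta_w < 10.0 * tol)
        if done.any():
            out_w[idx[done]] = w[done]
            out_k[idx[done]] = k[done]
            keep = ~done
            if not keep.any():
                return out_w, out_k
            idx, w, k = idx[keep], w[keep], k[keep]
            m_act, n_act = m_act[keep], n_act[keep]
    out_w[idx] = w
    out_k[idx] = k
    return out_w, out_k


def permutation_test(
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    model: ModelSpec | str = "M4",
    n_iter: int = 5000,
    seed: Optional[int] = None,
    component: str = "schema",
    n_starts: int = 10,
    batch_size: int = 512,
) -> PermutationResult:
    """Permutation test of the group difference in mean component responsibility.

    The observed statistic fits the model to each group's pooled trials
    (multi-start direct optimizer) and takes the difference (group A minus
    group B) of the mean posterior responsibility of ``component``.  The null
    distribution reassigns *participants* (group sizes preserved) and refits
    the pooled model per permuted group with the vectorised EM engine.
    """
    if isinstance(model, str):
        model = MODELS[model]
    if component == "schema" and not model.has_schema:
        raise ValueError(f"model {model.model_id} has no schema component")
    parts_a = sorted(trials_a["participant_id"].unique())
    parts_b = sorted(trials_b["participant_id"].unique())
    if len(parts_a) < 2 or len(parts_b) < 2:
        raise ValueError("permutation test needs >= 2 participants per group")
    overlap = set(parts_a) & set(parts_b)
    if overlap:
        raise ValueError(f"participants appear in both groups: {sorted(overlap)[:5]}")

    fit_a = fit_model(model, trials_a, n_starts=n_starts, seed=seed)
    fit_b = fit_model(model, trials_b, n_starts=n_starts, seed=seed)
    obs_a = mean_component_probability(responsibilities(fit_a, trials_a), component)
    obs_b = mean_component_probability(responsibilities(fit_b, trials_b), component)
    observed = obs_a - obs_b

    pooled = pd.concat([trials_a, trials_b], ignore_index=True)
    cos_t, cos_s = _prepare(model, pooled, allow_missing=True)
    resp_ok = np.isfinite(pooled["response"].to_numpy(float))
    part_of_trial = pd.Categorical(
        pooled.loc[resp_ok, "participant_id"], categories=parts_a + parts_b
    ).codes
    n_parts = len(parts_a) + len(parts_b)

    # warm start every permutation from the all-data pooled fit
    init_fit = fit_model(model, pooled, n_starts=n_starts, seed=seed)
    comp_idx = list(model.components).index(component)

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    done = 0
    while done < n_iter:
        b = min(batch_size, n_iter - done)
        assign = np.zeros((b, n_parts), dtype=bool)
        for i in range(b):
            assign[i, rng.permutation(n_parts)[: len(parts_a)]] = True
        mask_a = assign[:, part_of_trial].astype(float)
        w_a, _ = _em_engine(cos_t, cos_s, mask_a, init_fit.params)
        w_b, _ = _em_engine(cos_t, cos_s, 1.0 - mask_a, init_fit.params)
        null[done : done + b] = w_a[:, comp_idx] - w_b[:, comp_idx]
        done += b

    hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p_plain = hits / n_iter
    p_add_one = (hits + 1) / (n_iter + 1)
    return PermutationResult(
        observed_diff=float(observed),
        null_diffs=null,
        p_two_tailed=float(p_plain),
        p_add_one=float(p_add_one),
        n_iter=n_iter,
        seed=seed,
        observed_a=float(obs_a),
        observed_b=float(obs_b),
    )


# ---------------------------------------------------------------------------
# schema strength and correlational analyses
# ---------------------------------------------------------------------------

def schema_strength(trials: pd.DataFrame, phase: str = "IS") -> pd.DataFrame:
    """Initial schema strength per participant and category.

    Defined on Initial Study test trials as mean absolute error on
    outside-quadrant trials minus mean absolute error on inside-quadrant
    trials; positive values mean the participant was selectively better
    inside the schema quadrant.  Raises if any participant-category cell
    lacks inside or outside trials.
    """
    sub = trials[trials["phase"] == phase].copy()
    if len(sub) == 0:
        raise ValueError(f"no trials in phase {phase!r}")
    sub = sub[np.isfinite(sub["response"].to_numpy(float))]
    sub["abs_error"] = abs_error(
        sub["target"].to_numpy(float), sub["response"].to_numpy(float)
    )
    rows = []
    for (pid, cat), cell in sub.groupby(["participant_id", "category"], sort=True):
        means = cell.groupby("quadrant")["abs_error"].mean()
        if "inside" not in means or "outside" not in means:
            raise ValueError(
                f"participant {pid}, category {cat}: need both inside and outside trials"
            )
        rows.append(
            {
                "participant_id": pid,
                "group": cell["group"].iloc[0],
                "category": cat,
                "category_role": cell["category_role"].iloc[0],
                "strength": float(means["outside"] - means["inside"]),
            }
        )
    return pd.DataFrame(rows)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; requires n >= 3, finite values, variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_correlation needs two equal-length vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher r-to-z test of equality of two independent correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p_two_tailed: float


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> CorrelationComparison:
    """Compare two independent Pearson correlations via the Fisher transform.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-tailed normal p-value; antisymmetric in swapping the two samples.
    """
    for r in (r1, r2):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"correlations must satisfy |r| < 1, got {r}")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p_two_tailed=float(p))


@dataclass
class RegressionResult:
    """OLS on z-scored variables: standardized betas, overall F, R-squared."""

    betas: Dict[str, float]
    p_values: Dict[str, float]
    f_stat: float
    f_pvalue: float
    r_squared: float
    n: int


def standardized_regression(y, predictors: pd.DataFrame | Dict[str, Sequence[float]]) -> RegressionResult:
    """Ordinary least squares with all variables z-scored (standardized betas)."""
    x = pd.DataFrame(predictors).astype(float)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    if len(y) != n:
        raise ValueError("y and predictors must have the same length")
    if n <= k + 1:
        raise ValueError(f"need n > n_predictors + 1 (n={n}, k={k})")
    z = (x - x.mean()) / x.std(ddof=1)
    if not np.all(np.isfinite(z.to_numpy())):
        raise ValueError("constant predictor (zero variance) or non-finite values")
    zy = (y - y.mean()) / np.std(y, ddof=1)
    design = sm.add_constant(z)
    res = sm.OLS(zy, design).fit()
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    betas = {c: float(res.params[c]) for c in x.columns}
    pvals = {c: float(res.pvalues[c]) for c in x.columns}
    return RegressionResult(
        betas=betas,
        p_values=pvals,
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        n=n,
    )


# ---------------------------------------------------------------------------
# optional participant-level exclusion
# ---------------------------------------------------------------------------

def exclude_low_performers(trials: pd.DataFrame, n_sd: float = 2.0) -> pd.DataFrame:
    """Drop participants whose overall Final Test accuracy is an outlier.

    Performance is mean absolute error across all Final Test trials; a
    participant is excluded when their error exceeds the sample mean by more
    than ``n_sd`` standard deviations (performance more than ``n_sd`` SD
    below the group mean).  Off by default in the pipeline.
    """
    ft = trials[trials["phase"] == "FT"]
    ft = ft[np.isfinite(ft["response"].to_numpy(float))]
    err = pd.Series(
        abs_error(ft["target"].to_numpy(float), ft["response"].to_numpy(float)),
        index=ft.index,
    )
    per_part = err.groupby(ft["participant_id"]).mean()
    cutoff = per_part.mean() + n_sd * per_part.std(ddof=1)
    keep = per_part.index[per_part <= cutoff]
    return trials[trials["participant_id"].isin(keep)].copy()
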