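"""End-to-end analysis pipeline mirroring the study's Results structure.

Stages, in order:

1. **Cell means** — per-participant mean absolute error by phase x quadrant
   for the consistent category (Initial Study, the relevant New Learning
   phase, and the Final Test critical items), plus group-level summaries.
   These are the condition cells that feed a conventional mixed ANOVA, which
   is deliberately left to general-purpose statistics software.
2. **Schematization model comparison** — M1 vs M2 on consistent-category
   Final Test critical items, pooled per group.
3. **Schema-updating model comparison** — M3/M4/M5 on inconsistent-category
   Final Test critical items, pooled per group, with alternative-minus-
   preferred AIC/BIC deltas.
4. **Attribution + permutation** — mean old-schema responsibility per group
   under M4 and the participant-level permutation test; the same check on
   the immediate New Learning test trials.
5. **Schema strength** — per-subject M4/M2 fits, correlations of initial
   schema strength with later old-schema (inconsistent) and schema
   (consistent) responding, Fisher r-to-z comparisons between groups, and
   the two-predictor standardized regression.

A stage that fails is recorded and downstream stages that need its output
are skipped with an explicit notice; independent stages still run.
"""

from __future__ import annotations

import json
import logging
import time
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .circular import abs_error
from .design import GROUPS, relevant_nl_phase
from .inference import (
    compare_independent_correlations,
    exclude_low_performers,
    mean_component_probability,
    pearson_correlation,
    permutation_test,
    responsibilities,
    schema_strength,
    standardized_regression,
)
from .models import MODELS, compare_models, fit_model

logger = logging.getLogger("circschema")

__all__ = ["run_analysis", "critical_trials", "nl_test_trials"]


def critical_trials(trials: pd.DataFrame, role: str, group: Optional[str] = None) -> pd.DataFrame:
    """Final Test rows for critical items of one category role."""
    sel = (trials["phase"] == "FT") & trials["is_critical"] & (
        trials["category_role"] == role
    )
    if group is not None:
        sel &= trials["group"] == group
    return trials[sel]


def nl_test_trials(trials: pd.DataFrame, role: str, group: str) -> pd.DataFrame:
    """Immediate test rows from the group's relevant New Learning phase."""
    phase = relevant_nl_phase(group)
    sel = (
        (trials["phase"] == phase)
        & (trials["group"] == group)
        & (trials["category_role"] == role)
    )
    return trials[sel]


def _with_abs_error(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials[np.isfinite(trials["response"].to_numpy(float))].copy()
    out["abs_error"] = abs_error(out["target"].to_numpy(float), out["response"].to_numpy(float))
    return out


def _stage_cell_means(trials: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    parts = []
    for group in GROUPS:
        nl = relevant_nl_phase(group)
        g = trials[trials["group"] == group]
        is_rows = g[(g["phase"] == "IS") & (g["category_role"] == "consistent")]
        nl_rows = g[(g["phase"] == nl) & (g["category_role"] == "consistent")]
        ft_rows = critical_trials(g, "consistent")
        for label, rows in (("IS", is_rows), ("NL", nl_rows), ("FT", ft_rows)):
            rows = _with_abs_error(rows)
            cell = (
                rows.groupby(["participant_id", "quadrant"], sort=True)["abs_error"]
                .mean()
                .reset_index()
            )
            cell.insert(0, "group", group)
            cell.insert(1, "phase", label)
            parts.append(cell)
    per_participant = pd.concat(parts, ignore_index=True)
    summary = (
        per_participant.groupby(["group", "phase", "quadrant"], sort=True)["abs_error"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return {"per_participant": per_participant, "summary": summary}


def _fit_row(scope: str, group: str, fit) -> dict:
    return {
        "scope": scope,
        "group": group,
        "model_id": fit.model.model_id,
        "kappa": fit.kappa,
        "p_target": fit.p_target,
        "p_schema": np.nan if fit.p_schema is None else fit.p_schema,
        "p_guess": fit.p_guess,
        "log_likelihood": fit.log_likelihood,
        "n_trials": fit.n_trials,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_starts_converged": fit.n_starts_converged,
        "degenerate": fit.degenerate,
    }


def run_analysis(
    trials: pd.DataFrame,
    n_iter: int = 5000,
    seed: Optional[int] = None,
    n_starts: int = 10,
    exclude_outliers: bool = False,
    per_subject: bool = True,
) -> dict:
    """Run the full analysis; returns a dict of tables and scalar results.

    Keys: ``cell_means`` (dict of DataFrames), ``fits`` (DataFrame),
    ``comparisons`` (dict), ``attribution`` (dict), ``schema_strength``
    (dict), ``stages`` (per-stage status/wall-time log).
    """
    results: dict = {"stages": []}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
            status = "ok"
        except Exception as exc:  # isolate stage failures
            logger.exception("stage %s failed", name)
            out = None
            status = f"failed: {exc}"
        results["stages"].append(
            {"stage": name, "status": status, "seconds": round(time.perf_counter() - t0, 3)}
        )
        return out

    if exclude_outliers:
        n_before = trials["participant_id"].nunique()
        trials = exclude_low_performers(trials)
        logger.info(
            "outlier filter: %d -> %d participants", n_before, trials["participant_id"].nunique()
        )

    results["cell_means"] = run_stage("cell_means", lambda: _stage_cell_means(trials))

    fit_rows = []

    def stage_consistent():
        out = {}
        for group in GROUPS:
            rows = critical_trials(trials, "consistent", group)
            cmp = compare_models(rows, ["M1", "M2"], n_starts=n_starts, seed=seed)
            for mid, fit in cmp.fits.items():
                fit_rows.append(_fit_row("FT_consistent_pooled", group, fit))
            out[group] = {
                "preferred": cmp.preferred,
                "aic_delta_m1_m2": cmp.aic_delta("M1", "M2"),
                "bic_delta_m1_m2": cmp.bic_delta("M1", "M2"),
            }
        return out

    def stage_inconsistent():
        out = {}
        for group in GROUPS:
            rows = critical_trials(trials, "inconsistent", group)
            cmp = compare_models(rows, ["M3", "M4", "M5"], n_starts=n_starts, seed=seed)
            for mid, fit in cmp.fits.items():
                fit_rows.append(_fit_row("FT_inconsistent_pooled", group, fit))
            out[group] = {
                "preferred": cmp.preferred,
                "aic_delta_m3_m4": cmp.aic_delta("M3", "M4"),
                "bic_delta_m3_m4": cmp.bic_delta("M3", "M4"),
                "aic_delta_m5_m4": cmp.aic_delta("M5", "M4"),
                "bic_delta_m5_m4": cmp.bic_delta("M5", "M4"),
            }
        return out

    results["comparisons"] = {
        "consistent": run_stage("model_comparison_consistent", stage_consistent),
        "inconsistent": run_stage("model_comparison_inconsistent", stage_inconsistent),
    }

    def stage_attribution():
        ft = {g: critical_trials(trials, "inconsistent", g) for g in GROUPS}
        perm = permutation_test(
            ft[GROUPS[0]], ft[GROUPS[1]], "M4", n_iter=n_iter, seed=seed, n_starts=n_starts
        )
        nl_probs = {}
        for g in GROUPS:
            rows = nl_test_trials(trials, "inconsistent", g)
            fit = fit_model(MODELS["M4"], rows, n_starts=n_starts, seed=seed)
            fit_rows.append(_fit_row("NL_inconsistent_pooled", g, fit))
            ok = rows[np.isfinite(rows["response"].to_numpy(float))]
            nl_probs[g] = mean_component_probability(responsibilities(fit, ok), "schema")
        nl_perm = permutation_test(
            nl_test_trials(trials, "inconsistent", GROUPS[0]),
            nl_test_trials(trials, "inconsistent", GROUPS[1]),
            "M4",
            n_iter=n_iter,
            seed=seed,
            n_starts=n_starts,
        )
        return {
            "ft_mean_old_schema": {GROUPS[0]: perm.observed_a, GROUPS[1]: perm.observed_b},
            "ft_permutation_p": perm.p_two_tailed,
            "ft_permutation_p_add_one": perm.p_add_one,
            "ft_observed_diff": perm.observed_diff,
            "nl_mean_old_schema": nl_probs,
            "nl_permutation_p": nl_perm.p_two_tailed,
            "n_iter": n_iter,
        }

    results["attribution"] = run_stage("attribution_permutation", stage_attribution)

    def stage_schema_strength():
        if not per_subject:
            return {"skipped": "per_subject disabled"}
        strengths = schema_strength(trials)
        per_subj = []
        for g in GROUPS:
            for pid in sorted(trials.loc[trials["group"] == g, "participant_id"].unique()):
                p_tr = trials[trials["participant_id"] == pid]
                row = {"participant_id": pid, "group": g}
                for role, colname in (("inconsistent", "strength_inconsistent"),
                                      ("consistent", "strength_consistent")):
                    s = strengths[
                        (strengths["participant_id"] == pid)
                        & (strengths["category_role"] == role)
                    ]
                    row[colname] = float(s["strength"].iloc[0])
                ft_inc = critical_trials(p_tr, "inconsistent")
                fit4 = fit_model(MODELS["M4"], ft_inc, n_starts=n_starts, seed=seed)
                row["p_old_schema_ft"] = fit4.p_schema
                nl_inc = nl_test_trials(p_tr, "inconsistent", g)
                fit4nl = fit_model(MODELS["M4"], nl_inc, n_starts=n_starts, seed=seed)
                row["p_old_schema_nl"] = fit4nl.p_schema
                ft_con = critical_trials(p_tr, "consistent")
                fit2 = fit_model(MODELS["M2"], ft_con, n_starts=n_starts, seed=seed)
                row["p_schema_ft_consistent"] = fit2.p_schema
                per_subj.append(row)
        table = pd.DataFrame(per_subj)

        out = {"per_subject": table}
        corr: dict = {}
        for role, xcol, ycol in (
            ("inconsistent", "strength_inconsistent", "p_old_schema_ft"),
            ("consistent", "strength_consistent", "p_schema_ft_consistent"),
        ):
            rs = {}
            for g in GROUPS:
                sub = table[table["group"] == g]
                rs[g] = {
                    "r": pearson_correlation(sub[xcol], sub[ycol]),
                    "n": len(sub),
                }
            comparison = compare_independent_correlations(
                rs[GROUPS[0]]["r"], rs[GROUPS[0]]["n"], rs[GROUPS[1]]["r"], rs[GROUPS[1]]["n"]
            )
            corr[role] = {
                "by_group": rs,
                "z": comparison.z,
                "p_two_tailed": comparison.p_two_tailed,
            }
        out["correlations"] = corr

        regressions = {}
        for g in GROUPS:
            sub = table[table["group"] == g]
            reg = standardized_regression(
                sub["p_old_schema_ft"],
                sub[["strength_inconsistent", "p_old_schema_nl"]],
            )
            regressions[g] = {
                "betas": reg.betas,
                "p_values": reg.p_values,
                "f_stat": reg.f_stat,
                "f_pvalue": reg.f_pvalue,
                "r_squared": reg.r_squared,
                "n": reg.n,
            }
        out["regressions"] = regressions
        return out

    results["schema_strength"] = run_stage("schema_strength", stage_schema_strength)
    results["fits"] = pd.DataFrame(fit_rows)
    return results


def results_to_json(results: dict) -> str:
    """Serialize the scalar parts of an analysis result to pretty JSON."""

    def scrub(obj):
        if isinstance(obj, dict):
            return {k: scrub(v) for k, v in obj.items() if not isinstance(v, pd.DataFrame)}
        if isinstance(obj, (list, tuple)):
            return [scrub(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return json.dumps(scrub(results), indent=2, sort_keys=True)
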