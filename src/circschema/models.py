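"""Von Mises mixture models of continuous-report responses (Models 1-5).

All five models share the standard-mixture backbone: a von Mises component
centred on the trial's target (concentration ``kappa``) plus a uniform
guessing component.  Three of them add a second von Mises component — with
the *same* kappa, so they carry exactly one extra free parameter — centred on
a schema mean:

====== ======================== =========================================
model  components               schema component centred on
====== ======================== =========================================
M1     target + uniform         — (consistent-category Final Test data)
M2     M1 + schema              current schema mean (at learning)
M3     target + uniform         — (inconsistent-category Final Test data)
M4     M3 + schema              *original* (old, superseded) schema mean
M5     M3 + schema              *new* schema mean (current at learning)
====== ======================== =========================================

Free parameters: ``p_guess`` and ``kappa`` (2) for M1/M3, plus the schema
weight ``p_schema`` (3) for M2/M4/M5; ``p_target = 1 - p_guess - p_schema``.

Fitting is maximum likelihood by multi-start quasi-Newton ascent over
transformed parameters (log-kappa, softmax weights) with an analytic
gradient; an EM fitter over the same likelihood is provided as an
independent cross-check and as the engine behind vectorised permutation
refits.  Model comparison uses AIC and BIC.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import i0e, i1e, logsumexp

from .circular import circ_dist

__all__ = [
    "ModelSpec",
    "MODELS",
    "MixtureParams",
    "FitResult",
    "ModelComparison",
    "trial_loglik",
    "fit_model",
    "fit_model_em",
    "information_criteria",
    "compare_models",
]

_DEG2RAD = np.pi / 180.0
_LOG_DEG_JACOBIAN = np.log(_DEG2RAD)
_LOG_UNIFORM = -np.log(360.0)

#: kappa guard: above ~200 the von Mises is sharper than a 1-degree dial step
KAPPA_MAX = 200.0
KAPPA_MIN = 1e-4

_SCHEMA_COLUMN = {"current": "schema_mean_current", "original": "schema_mean_original"}


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one mixture model: which components, centred where."""

    model_id: str
    schema_centre: Optional[str]  # None, "current" or "original"
    description: str = ""

    def __post_init__(self):
        if self.schema_centre not in (None, "current", "original"):
            raise ValueError(f"invalid schema_centre {self.schema_centre!r}")

    @property
    def has_schema(self) -> bool:
        return self.schema_centre is not None

    @property
    def components(self) -> Tuple[str, ...]:
        if self.has_schema:
            return ("target", "schema", "guess")
        return ("target", "guess")

    @property
    def n_free_params(self) -> int:
        return 3 if self.has_schema else 2

    @property
    def schema_column(self) -> Optional[str]:
        return None if self.schema_centre is None else _SCHEMA_COLUMN[self.schema_centre]


MODELS: Dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", None, "standard mixture (consistent category)"),
    "M2": ModelSpec("M2", "current", "standard + schema mean"),
    "M3": ModelSpec("M3", None, "standard mixture (inconsistent category)"),
    "M4": ModelSpec("M4", "original", "standard + original (old) schema mean"),
    "M5": ModelSpec("M5", "current", "standard + new schema mean"),
}


@dataclass(frozen=True)
class MixtureParams:
    """Parameter vector of a mixture model; ``p_schema`` is None for M1/M3."""

    kappa: float
    p_guess: float
    p_schema: Optional[float] = None

    def __post_init__(self):
        ps = 0.0 if self.p_schema is None else self.p_schema
        if not (0.0 <= self.p_guess <= 1.0 and 0.0 <= ps <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if self.p_guess + ps > 1.0 + 1e-12:
            raise ValueError("p_guess + p_schema must not exceed 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def p_target(self) -> float:
        return max(0.0, 1.0 - self.p_guess - (self.p_schema or 0.0))


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model on one trial set."""

    model: ModelSpec
    params: MixtureParams
    log_likelihood: float
    n_trials: int
    aic: float
    bic: float
    n_starts: int = 0
    n_starts_converged: int = 0
    degenerate: bool = False

    @property
    def kappa(self) -> float:
        return self.params.kappa

    @property
    def p_guess(self) -> float:
        return self.params.p_guess

    @property
    def p_schema(self) -> Optional[float]:
        return self.params.p_schema

    @property
    def p_target(self) -> float:
        return self.params.p_target


def _prepare(model: ModelSpec, trials: pd.DataFrame, allow_missing: bool = True):
    """Cosine sufficient statistics: cos of response-target / response-schema distance."""
    resp = trials["response"].to_numpy(float)
    ok = np.isfinite(resp)
    if not allow_missing and not ok.all():
        raise ValueError("trials with missing responses cannot be scored")
    tgt = trials["target"].to_numpy(float)[ok]
    resp = resp[ok]
    cos_t = np.cos(np.asarray(circ_dist(resp, tgt)) * _DEG2RAD)
    cos_s = None
    if model.has_schema:
        col = model.schema_column
        if col not in trials.columns:
            raise ValueError(f"model {model.model_id} requires column {col!r}")
        centre = trials[col].to_numpy(float)[ok]
        if not np.all(np.isfinite(centre)):
            raise ValueError(f"model {model.model_id}: non-finite schema means in {col!r}")
        cos_s = np.cos(np.asarray(circ_dist(resp, centre)) * _DEG2RAD)
    return cos_t, cos_s


def _log_norm(kappa: np.ndarray | float):
    """log of the von Mises normalizer 2*pi*I0(kappa), stable via i0e."""
    return np.log(2.0 * np.pi * i0e(kappa)) + kappa


def _component_logliks(cos_t, cos_s, params: MixtureParams):
    """Stacked per-trial log densities (per degree) weighted by mixing weights."""
    k = params.kappa
    log_c = _log_norm(k)
    parts = []
    with np.errstate(divide="ignore", invalid="ignore"):
        parts.append(np.log(params.p_target) + k * cos_t - log_c + _LOG_DEG_JACOBIAN)
        if cos_s is not None:
            ps = params.p_schema or 0.0
            parts.append(np.log(ps) + k * cos_s - log_c + _LOG_DEG_JACOBIAN)
        parts.append(np.log(params.p_guess) + np.full_like(cos_t, _LOG_UNIFORM))
    return np.vstack(parts)


def trial_loglik(model: ModelSpec, params: MixtureParams, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial log mixture density (per degree) at the given parameters.

    Raises on missing responses; weights must lie on the simplex (enforced by
    :class:`MixtureParams`).  M4 with ``p_schema = 0`` reproduces the M3
    likelihood exactly.
    """
    if model.has_schema and params.p_schema is None:
        raise ValueError(f"model {model.model_id} requires p_schema")
    if not model.has_schema and params.p_schema not in (None, 0.0):
        raise ValueError(f"model {model.model_id} has no schema component")
    cos_t, cos_s = _prepare(model, trials, allow_missing=False)
    return logsumexp(_component_logliks(cos_t, cos_s, params), axis=0)


def information_criteria(log_likelihood: float, n_free_params: int, n_trials: int):
    """AIC = 2k - 2 logL and BIC = k ln(n) - 2 logL."""
    if n_trials <= 0:
        raise ValueError("information criteria need n_trials > 0")
    if not np.isfinite(log_likelihood):
        raise ValueError("log-likelihood must be finite")
    aic = 2.0 * n_free_params - 2.0 * log_likelihood
    bic = n_free_params * np.log(n_trials) - 2.0 * log_likelihood
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# direct maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _unpack(x: np.ndarray, has_schema: bool):
    """x = (a_schema?, a_guess, log kappa) -> weights (target, schema?, guess), kappa."""
    logits = np.concatenate([[0.0], x[:-1]])  # target logit pinned at 0
    w = np.exp(logits - logsumexp(logits))
    kappa = float(np.exp(x[-1]))
    return w, kappa


def _nll_and_grad(x: np.ndarray, cos_t: np.ndarray, cos_s: Optional[np.ndarray]):
    has_schema = cos_s is not None
    w, kappa = _unpack(x, has_schema)
    log_c = _log_norm(kappa)
    rows = [np.log(w[0]) + kappa * cos_t - log_c + _LOG_DEG_JACOBIAN]
    if has_schema:
        rows.append(np.log(w[1]) + kappa * cos_s - log_c + _LOG_DEG_JACOBIAN)
    rows.append(np.log(w[-1]) + np.full_like(cos_t, _LOG_UNIFORM))
    comp = np.vstack(rows)
    ll_i = logsumexp(comp, axis=0)
    nll = -float(ll_i.sum())

    r = np.exp(comp - ll_i)  # responsibilities, components x trials
    n = cos_t.shape[0]
    # softmax logits (free components: schema?, guess)
    grad_logits = -(r.sum(axis=1)[1:] - n * w[1:])
    a_k = i1e(kappa) / i0e(kappa)
    vm_cos = r[0] @ cos_t
    vm_mass = r[0].sum()
    if has_schema:
        vm_cos += r[1] @ cos_s
        vm_mass += r[1].sum()
    grad_logk = -kappa * (vm_cos - vm_mass * a_k)
    return nll, np.concatenate([grad_logits, [grad_logk]])


def _default_starts(has_schema: bool, n_starts: int, rng: np.random.Generator):
    def pack(p_schema, p_guess, kappa):
        p_target = 1.0 - p_guess - p_schema
        a_g = np.log(p_guess / p_target)
        if has_schema:
            a_s = np.log(max(p_schema, 1e-6) / p_target)
            return np.array([a_s, a_g, np.log(kappa)])
        return np.array([a_g, np.log(kappa)])

    fixed = [
        pack(0.10 if has_schema else 0.0, 0.10, 10.0),
        pack(0.30 if has_schema else 0.0, 0.10, 30.0),
        pack(0.001 if has_schema else 0.0, 0.05, 15.0),
        pack(0.45 if has_schema else 0.0, 0.30, 5.0),
    ]
    starts = fixed[: max(n_starts, 1)]
    while len(starts) < n_starts:
        if has_schema:
            starts.append(
                np.array(
                    [rng.uniform(-4, 1.5), rng.uniform(-4, 1.5), rng.uniform(np.log(1), np.log(100))]
                )
            )
        else:
            starts.append(np.array([rng.uniform(-4, 1.5), rng.uniform(np.log(1), np.log(100))]))
    return starts


def fit_model(
    model: ModelSpec,
    trials: pd.DataFrame,
    n_starts: int = 10,
    tol: float = 1e-6,
    seed: int | None = None,
    extra_starts: Sequence[MixtureParams] = (),
) -> FitResult:
    """Maximum-likelihood fit of one model on a trial set.

    Multi-start L-BFGS-B over (softmax weight logits, log kappa) with an
    analytic gradient; kappa is bounded in ``[KAPPA_MIN, KAPPA_MAX]``.  Trials
    with missing responses are excluded.  ``extra_starts`` lets callers seed
    the search with, e.g., a nested model's solution.

    Raises ``RuntimeError`` if no start converges; flags the fit degenerate
    when kappa ends on the guard bound (e.g. all responses identical).
    """
    cos_t, cos_s = _prepare(model, trials, allow_missing=True)
    n = cos_t.shape[0]
    if n < 1:
        raise ValueError("fit_model needs at least one trial with a response")
    rng = np.random.default_rng(seed)
    starts = _default_starts(model.has_schema, n_starts, rng)
    for p in extra_starts:
        pt = max(p.p_target, 1e-9)
        x = [np.log(np.clip(p.kappa, KAPPA_MIN, KAPPA_MAX))]
        x.insert(0, np.log(max(p.p_guess, 1e-9) / pt))
        if model.has_schema:
            x.insert(0, np.log(max(p.p_schema or 1e-9, 1e-9) / pt))
        starts.append(np.array(x))

    bounds = [(-30.0, 30.0)] * (len(starts[0]) - 1) + [
        (np.log(KAPPA_MIN), np.log(KAPPA_MAX))
    ]
    best = None
    n_conv = 0
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            args=(cos_t, cos_s),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol * 1e-4, "gtol": 1e-8, "maxiter": 500},
        )
        if res.success:
            n_conv += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or n_conv == 0:
        raise RuntimeError(
            f"fit_model({model.model_id}): no start converged over {len(starts)} starts"
        )

    w, kappa = _unpack(best.x, model.has_schema)
    degenerate = kappa >= KAPPA_MAX * 0.999
    if degenerate:
        warnings.warn(
            f"fit_model({model.model_id}): kappa hit the guard bound {KAPPA_MAX}; "
            "data may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    params = MixtureParams(
        kappa=min(kappa, KAPPA_MAX),
        p_guess=float(w[-1]),
        p_schema=float(w[1]) if model.has_schema else None,
    )
    logl = -float(best.fun)
    aic, bic = information_criteria(logl, model.n_free_params, n)
    return FitResult(
        model=model,
        params=params,
        log_likelihood=logl,
        n_trials=n,
        aic=aic,
        bic=bic,
        n_starts=len(starts),
        n_starts_converged=n_conv,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# EM (cross-check fitter; also the kernel of the vectorised permutation engine)
# ---------------------------------------------------------------------------

def _a_inv(r: np.ndarray) -> np.ndarray:
    """Invert A(kappa) = I1/I0: mean resultant length -> concentration.

    Piecewise rational approximation (Best & Fisher) refined with Newton
    steps on the stable exponentially-scaled Bessel ratio.
    """
    orig_shape = np.shape(r)
    r = np.clip(np.atleast_1d(np.asarray(r, dtype=float)).ravel(), 0.0, 1.0 - 1e-12)
    small = r < 0.53
    mid = (r >= 0.53) & (r < 0.85)
    k = np.empty_like(r)
    k[small] = 2 * r[small] + r[small] ** 3 + 5 * r[small] ** 5 / 6
    k[mid] = -0.4 + 1.39 * r[mid] + 0.43 / (1 - r[mid])
    big = ~(small | mid)
    k[big] = 1.0 / (r[big] ** 3 - 4 * r[big] ** 2 + 3 * r[big])
    k = np.clip(k, KAPPA_MIN, KAPPA_MAX)
    for _ in range(3):
        a = i1e(k) / i0e(k)
        da = 1.0 - a / k - a * a
        k = np.clip(k - (a - r) / np.maximum(da, 1e-12), KAPPA_MIN, KAPPA_MAX)
    return k.reshape(orig_shape)


def em_update(cos_t, cos_s, weights, kappa, mask=None):
    """One EM step, vectorised over an arbitrary leading batch dimension.

    ``weights``: (..., C) with C = 2 or 3 ordered (target[, schema], guess);
    ``kappa``: (...,); ``mask``: optional (..., n) trial-inclusion weights.
    Returns updated (weights, kappa, loglik) where loglik is the *current*
    (pre-update) masked log-likelihood (per-radian units; constant offset
    from the per-degree convention, irrelevant for convergence checks).
    """
    weights = np.asarray(weights, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    batch = kappa.shape
    k = kappa[..., None]
    log_c = _log_norm(k)
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    rows = [logw[..., 0:1] + k * cos_t - log_c]
    if cos_s is not None:
        rows.append(logw[..., 1:2] + k * cos_s - log_c)
    rows.append(np.broadcast_to(logw[..., -1:] - np.log(2.0 * np.pi), rows[0].shape))
    comp = np.stack(rows, axis=0)  # C x batch x n
    ll_i = logsumexp(comp, axis=0)
    r = np.exp(comp - ll_i)
    if mask is None:
        mask = np.ones_like(ll_i)
    loglik = (mask * ll_i).sum(axis=-1)
    n_c = (r * mask).sum(axis=-1)  # C x batch
    n_tot = n_c.sum(axis=0)
    new_w = np.moveaxis(n_c, 0, -1) / n_tot[..., None]
    num = (r[0] * mask * cos_t).sum(axis=-1)
    vm_mass = n_c[0]
    if cos_s is not None:
        num = num + (r[1] * mask * cos_s).sum(axis=-1)
        vm_mass = vm_mass + n_c[1]
    resultant = np.clip(num / np.maximum(vm_mass, 1e-300), 0.0, 1.0)
    new_kappa = _a_inv(resultant).reshape(batch)
    return new_w, new_kappa, loglik


def fit_model_em(
    model: ModelSpec,
    trials: pd.DataFrame,
    init: Optional[MixtureParams] = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> FitResult:
    """EM fit of one model; independent of the quasi-Newton path.

    Monotone in the likelihood; used as a cross-check that the direct
    optimizer found the optimum, and in vectorised form for permutation
    refits.
    """
    cos_t, cos_s = _prepare(model, trials, allow_missing=True)
    n = cos_t.shape[0]
    if n < 1:
        raise ValueError("fit_model_em needs at least one trial with a response")
    if init is None:
        init = MixtureParams(
            kappa=10.0, p_guess=0.1, p_schema=0.1 if model.has_schema else None
        )
    if model.has_schema:
        w = np.array([init.p_target, init.p_schema or 0.1, init.p_guess])
    else:
        w = np.array([init.p_target, init.p_guess])
    kappa = np.asarray(init.kappa, dtype=float)
    last = -np.inf
    for _ in range(max_iter):
        w, kappa, ll = em_update(cos_t, cos_s, w, kappa)
        if abs(ll - last) < tol * (abs(ll) + 1.0):
            break
        last = ll
    # loglik at the final parameters (em_update reports the pre-update value)
    _, _, ll = em_update(cos_t, cos_s, w, kappa)
    logl_deg = float(ll) + n * _LOG_DEG_JACOBIAN
    params = MixtureParams(
        kappa=float(kappa),
        p_guess=float(w[-1]),
        p_schema=float(w[1]) if model.has_schema else None,
    )
    aic, bic = information_criteria(logl_deg, model.n_free_params, n)
    return FitResult(
        model=model,
        params=params,
        log_likelihood=logl_deg,
        n_trials=n,
        aic=aic,
        bic=bic,
        n_starts=1,
        n_starts_converged=1,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Fits of several models on the identical trial set.

    ``deltas_vs_preferred[m]`` is (AIC_m - AIC_preferred, BIC_m - BIC_preferred):
    alternative minus preferred, so positive numbers mean the preferred model
    wins (the orientation used to report schema-model advantages).
    """

    fits: Dict[str, FitResult]
    errors: Dict[str, str]
    preferred: str

    @property
    def deltas_vs_preferred(self) -> Dict[str, Tuple[float, float]]:
        ref = self.fits[self.preferred]
        return {
            m: (f.aic - ref.aic, f.bic - ref.bic) for m, f in self.fits.items()
        }

    def aic_delta(self, alternative: str, reference: str) -> float:
        return self.fits[alternative].aic - self.fits[reference].aic

    def bic_delta(self, alternative: str, reference: str) -> float:
        return self.fits[alternative].bic - self.fits[reference].bic


def compare_models(
    trials: pd.DataFrame,
    model_ids: Iterable[str] = ("M3", "M4", "M5"),
    n_starts: int = 10,
    seed: int | None = None,
) -> ModelComparison:
    """Fit several models on the same trials and rank them by AIC.

    Fits 2-parameter models first and feeds their solutions to the nested
    3-parameter models as extra starts, which enforces the likelihood nesting
    (a richer model never fits worse than the model it contains).  A model
    whose fit fails is recorded in ``errors`` without aborting the rest.
    """
    model_ids = list(model_ids)
    if len(model_ids) < 2:
        raise ValueError("compare_models needs at least two models")
    order = sorted(model_ids, key=lambda m: MODELS[m].n_free_params)
    fits: Dict[str, FitResult] = {}
    errors: Dict[str, str] = {}
    nested: list[MixtureParams] = []
    for mid in order:
        model = MODELS[mid]
        extra = []
        if model.has_schema:
            extra = [
                dataclasses.replace(p, p_schema=1e-6) for p in nested
            ]
        try:
            fit = fit_model(model, trials, n_starts=n_starts, seed=seed, extra_starts=extra)
        except (RuntimeError, ValueError) as exc:
            errors[mid] = str(exc)
            continue
        fits[mid] = fit
        if not model.has_schema:
            nested.append(MixtureParams(kappa=fit.kappa, p_guess=fit.p_guess, p_schema=None))
    if not fits:
        raise RuntimeError(f"all model fits failed: {errors}")
    preferred = min(fits, key=lambda m: fits[m].aic)
    return ModelComparison(fits=fits, errors=errors, preferred=preferred)
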