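"""Coefficient estimation for the three regression families.

Linear models use closed-form ordinary least squares; the two nonlinear
families use trust-region nonlinear least squares (scipy) with analytic
Jacobians and linearization-based starting values.  Non-convergence is
reported via a flag, never an exception — mirroring how a real analysis
simply records that a model failed to converge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .model_core import (
    VALID_MEASUREMENTS,
    Bone,
    FittedModel,
    MeasurementRecord,
    MeasurementType,
    ModelFamily,
    ModelSpec,
    composite_lengths,
    evaluate_model,
    model_gradient,
    nonlinear_family_for,
)

__all__ = [
    "FitResult",
    "fit_linear",
    "fit_nonlinear",
    "fit_all",
    "coefficient_significance",
    "MIN_PAIRS_PER_MODEL",
]

logger = logging.getLogger(__name__)

#: Measurements with fewer complete training pairs than this are skipped.
MIN_PAIRS_PER_MODEL = 20


class DegenerateDataError(ValueError):
    """Design matrix or response admits no identifiable fit."""


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``converged=False`` marks the model unusable for prediction; the
    objective is the sum of squared residuals in cm².
    """

    model: Optional[FittedModel]
    iterations: int
    objective: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be non-negative")


def _as_columns(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    bone: Bone = Bone.HUMERUS,
    measurement_type: MeasurementType = MeasurementType.LENGTH,
) -> FitResult:
    """Ordinary least squares ``y = a*x + b`` via the normal equations.

    Stores x̄ and Sxx on the fitted model, which the exact t-based
    prediction interval needs.  Always converges.
    """
    x, y = _as_columns(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    x_mean = x.mean()
    sxx = float(np.sum((x - x_mean) ** 2))
    if sxx == 0:
        raise DegenerateDataError("x is constant: slope is not identifiable")
    sxy = float(np.sum((x - x_mean) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    residual_sd = float(np.sqrt(sse / (n - 2)))
    spec = ModelSpec(bone, measurement_type, ModelFamily.LINEAR,
                     {"a": float(slope), "b": intercept})
    model = FittedModel(
        spec=spec,
        n=n,
        residual_sd=residual_sd,
        converged=True,
        x_mean=float(x_mean),
        sxx=sxx,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )
    return FitResult(model=model, iterations=1, objective=sse, converged=True,
                     message="ols closed form")


def _initial_guess(family: ModelFamily, x: np.ndarray, y: np.ndarray,
                   a_scale: float = 1.05) -> np.ndarray:
    """Linearization-based starting values.

    With a provisional asymptote a0 = a_scale * max(y), both families reduce
    to a line in x after a log / logit transform, giving b0 and c0.
    """
    a0 = a_scale * float(y.max())
    eps = 1e-9
    if family is ModelFamily.ASYMPTOTIC_EXPONENTIAL:
        # ln(a0 - y) = ln(b) - c x
        z = np.log(np.maximum(a0 - y, eps))
    else:
        # logit(y / a0) = -ln(b) + c x
        frac = np.clip(y / a0, eps, 1 - eps)
        z = np.log(frac / (1 - frac))
    slope, intercept = np.polyfit(x, z, 1)
    if family is ModelFamily.ASYMPTOTIC_EXPONENTIAL:
        c0 = max(-slope, 1e-8)
        b0 = float(np.exp(intercept))
    else:
        c0 = max(slope, 1e-8)
        b0 = float(np.exp(-intercept))
    return np.array([a0, max(b0, eps), c0])


def fit_nonlinear(
    family: ModelFamily,
    x: Sequence[float],
    y: Sequence[float],
    bone: Bone = Bone.HUMERUS,
    measurement_type: MeasurementType = MeasurementType.LENGTH,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> FitResult:
    """Nonlinear least squares for the asymptotic exponential or logistic
    family, minimizing Σ(yᵢ − f(xᵢ; θ))².

    Uses scipy's trust-region reflective solver with the analytic Jacobian.
    The parameter covariance is the scaled s²·(JᵀJ)⁻¹ at the solution.
    Failure to satisfy the convergence criteria within ``max_iter`` yields
    ``converged=False``, never an exception.
    """
    if family is ModelFamily.LINEAR:
        raise ValueError("use fit_linear for the linear family")
    x, y = _as_columns(x, y)
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 pairs, got {n}")
    if np.ptp(y) == 0:
        raise DegenerateDataError("y has no spread: parameters not identifiable")

    def _spec(theta: np.ndarray) -> ModelSpec:
        return ModelSpec(bone, measurement_type, family,
                         dict(zip(("a", "b", "c"), map(float, theta))))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return evaluate_model(_spec(theta), x) - y

    def jacobian(theta: np.ndarray) -> np.ndarray:
        return model_gradient(_spec(theta), x)

    best = None
    # multi-start over the provisional-asymptote inflation factor: the
    # first start almost always suffices on growth-shaped data
    for a_scale in (1.05, 1.2, 1.5, 2.0):
        try:
            theta0 = _initial_guess(family, x, y, a_scale)
        except (ValueError, np.linalg.LinAlgError):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                sol = optimize.least_squares(
                    residuals,
                    theta0,
                    jac=jacobian,
                    method="trf",
                    max_nfev=max_iter * 3,
                    xtol=tol,
                    ftol=tol,
                    gtol=1e-8,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.status > 0 and a_scale == 1.05:
            break

    if best is None:
        return FitResult(model=None, iterations=0, objective=float(np.inf) if n else 0.0,
                         converged=False, message="all starting values failed")

    theta = best.x
    sse = float(2.0 * best.cost)
    converged = bool(best.status > 0)
    residual_sd = float(np.sqrt(sse / (n - 3)))
    jac = jacobian(theta)
    jtj = jac.T @ jac
    covariance = None
    message = best.message
    try:
        covariance = residual_sd**2 * np.linalg.inv(jtj)
        covariance = 0.5 * (covariance + covariance.T)
    except np.linalg.LinAlgError:
        message += "; singular JtJ, covariance unavailable"

    model = FittedModel(
        spec=_spec(theta),
        n=n,
        residual_sd=residual_sd,
        converged=converged,
        param_covariance=covariance,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )
    return FitResult(model=model, iterations=int(best.nfev), objective=sse,
                     converged=converged, message=message)


def coefficient_significance(result: FitResult) -> dict[str, float]:
    """Two-sided Wald-t p-values per coefficient.

    Linear models use the classical OLS standard errors; nonlinear models
    use the delta-method covariance.  Reported, never used as a filter.
    """
    model = result.model
    if model is None:
        return {}
    spec = model.spec
    p = spec.family.n_params
    df = model.n - p
    if spec.family is ModelFamily.LINEAR:
        s = model.residual_sd
        se_a = s / np.sqrt(model.sxx)
        se_b = s * np.sqrt(1.0 / model.n + model.x_mean**2 / model.sxx)
        ses = {"a": se_a, "b": se_b}
    else:
        if model.param_covariance is None:
            return {}
        diag = np.sqrt(np.maximum(np.diag(model.param_covariance), 0.0))
        ses = dict(zip(("a", "b", "c"), diag))
    out = {}
    for name, se in ses.items():
        if se == 0:
            out[name] = 0.0
            continue
        t = float(spec.coefficients[name]) / se
        out[name] = float(2.0 * stats.t.sf(abs(t), df))
    return out


def fit_all(
    training: Sequence[MeasurementRecord],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> dict[tuple[Bone, MeasurementType, ModelFamily], FitResult]:
    """Attempt the full 40-model grid on a training cohort.

    Each of the 20 measurements (18 single-bone + 2 composite) gets a linear
    fit and its measurement-appropriate nonlinear fit (asymptotic exponential
    for lengths, logistic for breadths).  Pairs with a missing measurement
    are dropped per model (complete-case); measurements with fewer than
    ``MIN_PAIRS_PER_MODEL`` complete pairs are skipped with a warning.
    """
    records = [composite_lengths(r) for r in training]
    records = [r for r in records if r.known_stature_cm is not None]
    if not records:
        raise ValueError("no training records with known stature")
    results: dict[tuple[Bone, MeasurementType, ModelFamily], FitResult] = {}
    for key in sorted(VALID_MEASUREMENTS, key=lambda k: (k[0].value, k[1].value)):
        bone, mtype = key
        pairs = [(r.measurements[key], r.known_stature_cm)
                 for r in records if key in r.measurements]
        if len(pairs) < MIN_PAIRS_PER_MODEL:
            logger.warning(
                "skipping %s %s: only %d complete pairs (< %d)",
                bone.value, mtype.value, len(pairs), MIN_PAIRS_PER_MODEL,
            )
            continue
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        try:
            results[(bone, mtype, ModelFamily.LINEAR)] = fit_linear(x, y, bone, mtype)
        except DegenerateDataError as exc:
            results[(bone, mtype, ModelFamily.LINEAR)] = FitResult(
                model=None, iterations=0, objective=0.0, converged=False,
                message=str(exc))
        family = nonlinear_family_for(mtype)
        try:
            results[(bone, mtype, family)] = fit_nonlinear(
                family, x, y, bone, mtype, max_iter=max_iter, tol=tol)
        except DegenerateDataError as exc:
            results[(bone, mtype, family)] = FitResult(
                model=None, iterations=0, objective=0.0, converged=False,
                message=str(exc))
    return results
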