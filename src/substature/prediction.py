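"""Point estimates and prediction intervals for new individuals.

For a refitted linear model the interval is the exact t-based one,

    ŷ ± t_{n-2, 1-α/2} · s · sqrt(1 + 1/n + (x0 - x̄)²/Sxx),

and for the nonlinear families the first-order delta-method analogue,

    ŷ ± t_{n-p, 1-α/2} · s · sqrt(1 + g(x0)ᵀ (JᵀJ)⁻¹ g(x0)),

with g the parameter gradient at x0.  A residual-bootstrap interval is
available as an opt-in cross-check.  Published registry models print only
the residual SD, so their intervals use the conservative normal
approximation ŷ ± z_{1-α/2}·s and carry an explicit warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .model_core import (
    Bone,
    FittedModel,
    MeasurementRecord,
    MeasurementType,
    ModelFamily,
    RegistryEntry,
    composite_lengths,
    evaluate_model,
    model_gradient,
)
from .fitting import FitResult

__all__ = ["PredictionResult", "prediction_interval", "registry_prediction",
           "bootstrap_interval", "estimate_stature"]

#: Fraction of the training range beyond which a prediction is flagged
#: as extrapolation (warned, never refused).
EXTRAPOLATION_MARGIN = 0.10


@dataclass
class PredictionResult:
    """A stature estimate with its interval and provenance."""

    model_id: tuple[Bone, MeasurementType, ModelFamily]
    x: float
    point_cm: float
    pi_lower_cm: float
    pi_upper_cm: float
    level: float
    method: str  # {exact_t, delta_t, approx_z, bootstrap, unavailable}
    warnings: list[str] = field(default_factory=list)
    source_mad_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.pi_lower_cm <= self.point_cm <= self.pi_upper_cm):
            raise ValueError("interval must bracket the point estimate")

    @property
    def label(self) -> str:
        bone, mtype, family = self.model_id
        return f"{bone.value}_{mtype.value}~{family.value}"


def _check_level(level: float) -> None:
    if not (0.5 < level < 0.999):
        raise ValueError(f"level must lie in (0.5, 0.999), got {level}")


def _extrapolation_warning(model: FittedModel, x0: float) -> Optional[str]:
    if model.x_min is None or model.x_max is None:
        return None
    span = model.x_max - model.x_min
    lo = model.x_min - EXTRAPOLATION_MARGIN * span
    hi = model.x_max + EXTRAPOLATION_MARGIN * span
    if not (lo <= x0 <= hi):
        return (
            f"x={x0:.1f} mm is outside the training range "
            f"[{model.x_min:.1f}, {model.x_max:.1f}] mm (extrapolation)"
        )
    return None


def prediction_interval(
    model: FittedModel, x0: float, level: float = 0.95
) -> PredictionResult:
    """Level-``level`` prediction interval for a new individual at ``x0`` mm."""
    _check_level(level)
    if not model.converged:
        raise ValueError("model did not converge; prediction disabled")
    x0 = float(x0)
    spec = model.spec
    point = float(evaluate_model(spec, x0))
    p = spec.family.n_params
    df = model.n - p
    tq = float(stats.t.ppf(0.5 + level / 2.0, df))
    s = model.residual_sd
    warnings_list: list[str] = []
    extra = _extrapolation_warning(model, x0)
    if extra:
        warnings_list.append(extra)

    if spec.family is ModelFamily.LINEAR:
        if model.x_mean is None or model.sxx is None:
            method, half = "unavailable", 0.0
        else:
            method = "exact_t"
            half = tq * s * np.sqrt(
                1.0 + 1.0 / model.n + (x0 - model.x_mean) ** 2 / model.sxx
            )
    else:
        if model.param_covariance is None:
            method, half = "unavailable", 0.0
            warnings_list.append("parameter covariance unavailable; no interval")
        else:
            method = "delta_t"
            g = model_gradient(spec, x0)
            # param_covariance = s^2 (JtJ)^-1, so g' cov g = s^2 g'(JtJ)^-1 g
            var_mean = float(g @ model.param_covariance @ g)
            half = tq * np.sqrt(s**2 + max(var_mean, 0.0))
    if method == "unavailable":
        lower = upper = point
    else:
        lower, upper = point - half, point + half
    return PredictionResult(
        model_id=spec.key, x=x0, point_cm=point,
        pi_lower_cm=float(lower), pi_upper_cm=float(upper),
        level=level, method=method, warnings=warnings_list,
    )


def registry_prediction(
    entry: RegistryEntry, x0: float, level: float = 0.95
) -> PredictionResult:
    """Approximate interval from a published model's printed residual SD.

    Published tables omit n, x̄/Sxx and the parameter covariance, so the
    interval is ŷ ± z_{1-α/2}·s — slightly narrower than the exact one.
    """
    _check_level(level)
    x0 = float(x0)
    point = float(evaluate_model(entry.spec, x0))
    warnings_list = ["approximate normal interval from printed residual SD"]
    if entry.sanity_flag:
        warnings_list.append(
            "model is sanity-flagged (implausible prediction at a typical "
            "adult measurement); interpret with caution"
        )
    s = entry.residual_sd_cm
    if s is None:
        return PredictionResult(
            model_id=entry.spec.key, x=x0, point_cm=point,
            pi_lower_cm=point, pi_upper_cm=point, level=level,
            method="unavailable",
            warnings=warnings_list + ["no printed residual SD"],
        )
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * s
    return PredictionResult(
        model_id=entry.spec.key, x=x0, point_cm=point,
        pi_lower_cm=point - half, pi_upper_cm=point + half,
        level=level, method="approx_z", warnings=warnings_list,
        source_mad_cm=entry.mad_cm,
    )


def bootstrap_interval(
    model: FittedModel,
    x_train: Sequence[float],
    y_train: Sequence[float],
    x0: float,
    level: float = 0.95,
    n_boot: int = 500,
    seed: Optional[int] = None,
) -> PredictionResult:
    """Residual-bootstrap prediction interval (percentile form).

    Resamples fitted residuals, refits, and forms the percentile interval
    of ŷ*(x0) + e* over replicates.  Slower than the delta method; used to
    validate it on well-specified data.
    """
    from .fitting import fit_linear, fit_nonlinear  # local: avoid cycle at import

    _check_level(level)
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    rng = np.random.default_rng(seed)
    spec = model.spec
    fitted_vals = evaluate_model(spec, x)
    resid = y - fitted_vals
    resid = resid - resid.mean()
    point = float(evaluate_model(spec, float(x0)))
    draws = []
    for _ in range(n_boot):
        y_star = fitted_vals + rng.choice(resid, size=resid.size, replace=True)
        try:
            if spec.family is ModelFamily.LINEAR:
                res = fit_linear(x, y_star, spec.bone, spec.measurement_type)
            else:
                res = fit_nonlinear(spec.family, x, y_star,
                                    spec.bone, spec.measurement_type)
        except ValueError:
            continue
        if not res.converged or res.model is None:
            continue
        e_star = rng.choice(resid)
        draws.append(float(evaluate_model(res.model.spec, float(x0))) + e_star)
    if len(draws) < max(50, n_boot // 4):
        raise RuntimeError("too few successful bootstrap replicates")
    alpha = 1.0 - level
    lower, upper = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return PredictionResult(
        model_id=spec.key, x=float(x0), point_cm=point,
        pi_lower_cm=float(min(lower, point)), pi_upper_cm=float(max(upper, point)),
        level=level, method="bootstrap",
        warnings=[f"bootstrap percentile interval, B={len(draws)}"],
    )


ModelSet = Union[Sequence[RegistryEntry], dict]


def estimate_stature(
    record: MeasurementRecord,
    models: ModelSet,
    level: float = 0.95,
    family_preference: str = "both",
) -> list[PredictionResult]:
    """All available stature estimates for one individual.

    Composite limb lengths are derived first; then every available
    measurement is run through every matching model of the requested
    families.  Results are sorted most-precise-first by the source model's
    printed MAD (fitted models fall back to residual SD).  Estimates from
    sanity-flagged models carry a warning but are never suppressed.
    """
    _check_level(level)
    if family_preference not in ("both", "linear_first", "nonlinear_first",
                                 "linear", "nonlinear"):
        raise ValueError(f"unknown family preference {family_preference!r}")
    record = composite_lengths(record)
    results: list[PredictionResult] = []

    def _family_ok(family: ModelFamily) -> bool:
        if family_preference in ("both", "linear_first", "nonlinear_first"):
            return True
        if family_preference == "linear":
            return family is ModelFamily.LINEAR
        return family is not ModelFamily.LINEAR

    if isinstance(models, dict):
        # fitted set: (bone, mtype, family) -> FitResult or FittedModel
        for key, value in models.items():
            fitted = value.model if isinstance(value, FitResult) else value
            if fitted is None or not fitted.converged:
                continue
            if not _family_ok(fitted.spec.family):
                continue
            mkey = (fitted.spec.bone, fitted.spec.measurement_type)
            if mkey not in record.measurements:
                continue
            results.append(
                prediction_interval(fitted, record.measurements[mkey], level)
            )
    else:
        for entry in models:
            if not _family_ok(entry.spec.family):
                continue
            mkey = (entry.spec.bone, entry.spec.measurement_type)
            if mkey not in record.measurements:
                continue
            results.append(registry_prediction(entry, record.measurements[mkey], level))

    def _precision(r: PredictionResult) -> float:
        if r.source_mad_cm is not None:
            return r.source_mad_cm
        return (r.pi_upper_cm - r.pi_lower_cm) / 2.0 if r.method != "unavailable" else np.inf

    results.sort(key=_precision)
    return results
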