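"""Domain types, regression families, and the published-model registry.

Stature (cm) is modelled as a function of a single long-bone measurement
(mm) using one of three functional families:

* linear                   ``y = a*x + b``
* asymptotic exponential   ``y = a - b*exp(-c*x)``   (length measurements)
* three-parameter logistic ``y = a / (1 + b*exp(-c*x))`` (breadth measurements)

The registry embedded under ``data/published_models.json`` carries the 38
published pooled-sex equations (20 linear, 18 nonlinear) together with the
performance metrics reported alongside them (Kendall's tau, residual SD,
two-sample KS *D*, hold-out test accuracy, and MAD, all in the published
units).  Coefficients are stored exactly as printed; two entries whose
logistic rate constants are an order of magnitude out of family are kept
verbatim but permanently sanity-flagged.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "Bone",
    "MeasurementType",
    "ModelFamily",
    "ModelSpec",
    "FittedModel",
    "RegistryEntry",
    "MeasurementRecord",
    "MeasurementKey",
    "VALID_MEASUREMENTS",
    "SINGLE_BONE_MEASUREMENTS",
    "COMPOSITE_MEASUREMENTS",
    "COMPOSITE_COMPONENTS",
    "DEFAULT_REFERENCE_INPUTS",
    "REGISTRY_VERSION",
    "evaluate_model",
    "model_gradient",
    "invert_model",
    "attainable_range",
    "composite_lengths",
    "load_registry",
    "registry_sanity_check",
]


class InputError(ValueError):
    """Invalid numeric input to a model operation."""


class DomainError(ValueError):
    """Requested value lies outside a model's attainable range."""


class RegistryIntegrityError(RuntimeError):
    """Embedded registry asset is missing or corrupted."""


# ---------------------------------------------------------------------------
# Enumerations and measurement grid
# ---------------------------------------------------------------------------

class Bone(str, Enum):
    HUMERUS = "humerus"
    RADIUS = "radius"
    ULNA = "ulna"
    FEMUR = "femur"
    TIBIA = "tibia"
    FIBULA = "fibula"
    UPPER_LIMB = "upper_limb"  # humerus + radius length
    LOWER_LIMB = "lower_limb"  # femur + tibia length


class MeasurementType(str, Enum):
    LENGTH = "length"
    PROXIMAL_BREADTH = "proximal_breadth"
    MIDSHAFT_BREADTH = "midshaft_breadth"
    DISTAL_BREADTH = "distal_breadth"


MeasurementKey = tuple  # (Bone, MeasurementType)

COMPOSITE_BONES = frozenset({Bone.UPPER_LIMB, Bone.LOWER_LIMB})

COMPOSITE_COMPONENTS: dict[Bone, tuple[Bone, Bone]] = {
    Bone.UPPER_LIMB: (Bone.HUMERUS, Bone.RADIUS),
    Bone.LOWER_LIMB: (Bone.FEMUR, Bone.TIBIA),
}

# The per-bone measurement grid: 18 single-bone measurements.  The ulna has
# no proximal or distal breadth, the femur no proximal breadth, and the
# fibula contributes length only.
SINGLE_BONE_MEASUREMENTS: frozenset[MeasurementKey] = frozenset(
    {
        (Bone.HUMERUS, MeasurementType.LENGTH),
        (Bone.HUMERUS, MeasurementType.PROXIMAL_BREADTH),
        (Bone.HUMERUS, MeasurementType.MIDSHAFT_BREADTH),
        (Bone.HUMERUS, MeasurementType.DISTAL_BREADTH),
        (Bone.RADIUS, MeasurementType.LENGTH),
        (Bone.RADIUS, MeasurementType.PROXIMAL_BREADTH),
        (Bone.RADIUS, MeasurementType.MIDSHAFT_BREADTH),
        (Bone.RADIUS, MeasurementType.DISTAL_BREADTH),
        (Bone.ULNA, MeasurementType.LENGTH),
        (Bone.ULNA, MeasurementType.MIDSHAFT_BREADTH),
        (Bone.FEMUR, MeasurementType.LENGTH),
        (Bone.FEMUR, MeasurementType.MIDSHAFT_BREADTH),
        (Bone.FEMUR, MeasurementType.DISTAL_BREADTH),
        (Bone.TIBIA, MeasurementType.LENGTH),
        (Bone.TIBIA, MeasurementType.PROXIMAL_BREADTH),
        (Bone.TIBIA, MeasurementType.MIDSHAFT_BREADTH),
        (Bone.TIBIA, MeasurementType.DISTAL_BREADTH),
        (Bone.FIBULA, MeasurementType.LENGTH),
    }
)

COMPOSITE_MEASUREMENTS: frozenset[MeasurementKey] = frozenset(
    {
        (Bone.UPPER_LIMB, MeasurementType.LENGTH),
        (Bone.LOWER_LIMB, MeasurementType.LENGTH),
    }
)

#: All 20 admissible (bone, measurement type) pairs.
VALID_MEASUREMENTS: frozenset[MeasurementKey] = (
    SINGLE_BONE_MEASUREMENTS | COMPOSITE_MEASUREMENTS
)


class ModelFamily(str, Enum):
    LINEAR = "linear"
    ASYMPTOTIC_EXPONENTIAL = "asymptotic_exponential"
    LOGISTIC3 = "logistic3"

    @property
    def n_params(self) -> int:
        return 2 if self is ModelFamily.LINEAR else 3

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("a", "b") if self is ModelFamily.LINEAR else ("a", "b", "c")


#: Which nonlinear family Table-style model grids pair with each measurement.
def nonlinear_family_for(measurement_type: MeasurementType) -> ModelFamily:
    """Lengths use the asymptotic exponential; breadths the 3-par logistic."""
    if measurement_type is MeasurementType.LENGTH:
        return ModelFamily.ASYMPTOTIC_EXPONENTIAL
    return ModelFamily.LOGISTIC3


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A functional family with coefficients for one (bone, measurement).

    ``x`` denotes the measurement in millimetres, ``y`` the stature in
    centimetres.  Coefficients use the keys ``a``, ``b`` (linear: slope,
    intercept) and additionally ``c`` for the nonlinear families.
    """

    bone: Bone
    measurement_type: MeasurementType
    family: ModelFamily
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        if (self.bone, self.measurement_type) not in VALID_MEASUREMENTS:
            raise ValueError(
                f"({self.bone.value}, {self.measurement_type.value}) is not "
                "one of the 20 admissible measurements"
            )
        expected = self.family.param_names
        missing = [k for k in expected if k not in self.coefficients]
        if missing:
            raise ValueError(f"{self.family.value} model missing coefficients {missing}")
        for name in expected:
            if not math.isfinite(float(self.coefficients[name])):
                raise ValueError(f"coefficient {name} is not finite")

    @property
    def params(self) -> np.ndarray:
        return np.array([float(self.coefficients[k]) for k in self.family.param_names])

    @property
    def key(self) -> tuple[Bone, MeasurementType, ModelFamily]:
        return (self.bone, self.measurement_type, self.family)

    @property
    def label(self) -> str:
        return f"{self.bone.value}_{self.measurement_type.value}~{self.family.value}"

    def suspect_parameters(self) -> list[str]:
        """Soft validity flags: non-positive asymptote or rate constant.

        Violations are flagged, never rejected — the registry keeps printed
        coefficients verbatim.
        """
        flags: list[str] = []
        if self.family is not ModelFamily.LINEAR:
            a = float(self.coefficients["a"])
            c = float(self.coefficients["c"])
            if a <= 0:
                flags.append(f"asymptote a={a} is not positive")
            if c <= 0:
                flags.append(f"rate constant c={c} is not positive")
        return flags


@dataclass
class FittedModel:
    """A :class:`ModelSpec` with the fit metadata needed for prediction
    intervals: sample size, residual SD, and either (x̄, Sxx) for linear
    models or the scaled parameter covariance s²·(JᵀJ)⁻¹ for nonlinear ones.
    """

    spec: ModelSpec
    n: int
    residual_sd: float
    converged: bool
    x_mean: Optional[float] = None
    sxx: Optional[float] = None
    param_covariance: Optional[np.ndarray] = None
    x_min: Optional[float] = None
    x_max: Optional[float] = None

    def __post_init__(self) -> None:
        p = self.spec.family.n_params
        if self.n <= p:
            raise ValueError(f"n={self.n} must exceed the parameter count {p}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.param_covariance is not None:
            cov = np.asarray(self.param_covariance, dtype=float)
            if cov.shape != (p, p):
                raise ValueError(f"param_covariance must be {p}x{p}")
            if not np.allclose(cov, cov.T, atol=1e-8 * (1 + np.abs(cov).max())):
                raise ValueError("param_covariance must be symmetric")
            if np.any(np.diag(cov) < -1e-12):
                raise ValueError("param_covariance has negative diagonal")
            self.param_covariance = cov


@dataclass
class RegistryEntry:
    """One published model with its printed performance metadata."""

    spec: ModelSpec
    printed_metrics: dict[str, Optional[float]] = field(default_factory=dict)
    sanity_flag: bool = False

    @property
    def mad_cm(self) -> Optional[float]:
        return self.printed_metrics.get("mad_cm")

    @property
    def residual_sd_cm(self) -> Optional[float]:
        return self.printed_metrics.get("residual_sd_cm")


@dataclass
class MeasurementRecord:
    """One individual's long-bone measurements plus optional metadata.

    Measurements are millimetres, keyed by (bone, measurement type); known
    stature, when present, is centimetres.  ``measurement_kind`` records
    whether a value is a diaphyseal or maximum (epiphyses included)
    measurement; it is metadata only and never selects models.
    """

    id: str
    sex: str = "unknown"  # {"F", "M", "unknown"}
    age_years: Optional[float] = None
    known_stature_cm: Optional[float] = None
    measurements: dict[MeasurementKey, float] = field(default_factory=dict)
    measurement_kind: dict[MeasurementKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.known_stature_cm is not None and not (30 < self.known_stature_cm < 230):
            raise ValueError(
                f"known stature {self.known_stature_cm} cm outside plausible (30, 230)"
            )
        for key, value in self.measurements.items():
            if key not in VALID_MEASUREMENTS:
                raise ValueError(f"unknown measurement {key}")
            # composites sum two bones, so their bound is twice the single-bone one
            upper = 1400 if key[0] in COMPOSITE_BONES else 700
            if not (0 < value < upper):
                raise ValueError(
                    f"measurement {key[0].value} {key[1].value} = {value} mm "
                    f"outside plausible (0, {upper})"
                )
        for key, kind in self.measurement_kind.items():
            if kind not in ("diaphyseal", "maximum", "unknown"):
                raise ValueError(f"measurement kind {kind!r} invalid for {key}")


# ---------------------------------------------------------------------------
# Family evaluation, gradients, inversion
# ---------------------------------------------------------------------------

_EXP_MAX = 700.0  # exp overflow guard; underflow quietly reaches 0.0


def _safe_exp(t):
    """exp with the argument clamped against overflow; underflow yields 0."""
    return np.exp(np.minimum(t, _EXP_MAX))


def evaluate_model(spec: ModelSpec, x):
    """Predicted stature (cm) for measurement ``x`` (mm).

    Accepts a scalar or array; x must be finite and non-negative (x = 0 is
    admitted as the curve's boundary value).
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("measurement x must be finite")
    if np.any(arr < 0):
        raise InputError("measurement x must be non-negative")
    a = float(spec.coefficients["a"])
    b = float(spec.coefficients["b"])
    if spec.family is ModelFamily.LINEAR:
        out = a * arr + b
    elif spec.family is ModelFamily.ASYMPTOTIC_EXPONENTIAL:
        c = float(spec.coefficients["c"])
        out = a - b * _safe_exp(-c * arr)
    else:
        c = float(spec.coefficients["c"])
        out = a / (1.0 + b * _safe_exp(-c * arr))
    return out.item() if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def model_gradient(spec: ModelSpec, x):
    """Analytic gradient of the prediction w.r.t. the parameters.

    Returns an array of shape ``(p,)`` for scalar x, ``(n, p)`` for a
    vector, ordered as the family's parameter names.
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise InputError("measurement x must be finite")
    if spec.family is ModelFamily.LINEAR:
        grad = np.column_stack([arr, np.ones_like(arr)])
    elif spec.family is ModelFamily.ASYMPTOTIC_EXPONENTIAL:
        b = float(spec.coefficients["b"])
        c = float(spec.coefficients["c"])
        e = _safe_exp(-c * arr)
        grad = np.column_stack([np.ones_like(arr), -e, b * arr * e])
    else:
        a = float(spec.coefficients["a"])
        b = float(spec.coefficients["b"])
        c = float(spec.coefficients["c"])
        e = _safe_exp(-c * arr)
        denom = 1.0 + b * e
        grad = np.column_stack(
            [1.0 / denom, -a * e / denom**2, a * b * arr * e / denom**2]
        )
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return grad[0]
    return grad


def attainable_range(spec: ModelSpec) -> tuple[float, float]:
    """Open interval of statures the model can produce for x in (0, inf).

    Linear models span the half-line starting at the intercept (slope sign
    permitting, effectively unbounded); the asymptotic exponential spans
    (a-b, a); the logistic spans (a/(1+b), a).
    """
    a = float(spec.coefficients["a"])
    b = float(spec.coefficients["b"])
    if spec.family is ModelFamily.LINEAR:
        if a > 0:
            return (b, math.inf)
        if a < 0:
            return (-math.inf, b)
        return (b, b)
    if spec.family is ModelFamily.ASYMPTOTIC_EXPONENTIAL:
        return (a - b, a)
    return (a / (1.0 + b), a)


def invert_model(spec: ModelSpec, y: float) -> float:
    """Measurement x (mm) producing stature ``y`` (cm); inverse of
    :func:`evaluate_model`.

    Raises :class:`DomainError` when ``y`` is not strictly inside the
    family's attainable range.
    """
    y = float(y)
    if not math.isfinite(y):
        raise InputError("stature y must be finite")
    a = float(spec.coefficients["a"])
    b = float(spec.coefficients["b"])
    lo, hi = attainable_range(spec)
    if spec.family is ModelFamily.LINEAR:
        if a == 0:
            raise DomainError("linear model with zero slope is not invertible")
        return (y - b) / a
    if not (lo < y < hi):
        raise DomainError(
            f"stature {y} cm outside the attainable interval ({lo:.6g}, {hi:.6g}) "
            f"of {spec.label}"
        )
    c = float(spec.coefficients["c"])
    if spec.family is ModelFamily.ASYMPTOTIC_EXPONENTIAL:
        return -math.log((a - y) / b) / c
    return -math.log((a / y - 1.0) / b) / c


# ---------------------------------------------------------------------------
# Composite limb lengths
# ---------------------------------------------------------------------------

def composite_lengths(record: MeasurementRecord) -> MeasurementRecord:
    """Return a copy with upper/lower limb lengths added where computable.

    Upper limb length = humerus + radius length; lower limb length =
    femur + tibia length.  Existing entries are never overwritten; a record
    missing either component is returned unchanged for that composite.
    """
    measurements = dict(record.measurements)
    kinds = dict(record.measurement_kind)
    for composite, (first, second) in COMPOSITE_COMPONENTS.items():
        key = (composite, MeasurementType.LENGTH)
        if key in measurements:
            continue
        k1 = (first, MeasurementType.LENGTH)
        k2 = (second, MeasurementType.LENGTH)
        if k1 in measurements and k2 in measurements:
            measurements[key] = measurements[k1] + measurements[k2]
    return replace(record, measurements=measurements, measurement_kind=kinds)


# ---------------------------------------------------------------------------
# Published-model registry
# ---------------------------------------------------------------------------

REGISTRY_VERSION = "1.0.0"
_REGISTRY_RESOURCE = "published_models.json"

# sha256 of the embedded asset, recorded at packaging time.
REGISTRY_SHA256 = "6489af288fb663901f4e17ed90cc2f3f4fe9d509f14d6f761f80a9e60a67c0db"

#: The two grid cells with no published nonlinear model (the nonlinear fits
#: for these breadths failed to converge in the source analysis).
MISSING_NONLINEAR: frozenset[MeasurementKey] = frozenset(
    {
        (Bone.TIBIA, MeasurementType.DISTAL_BREADTH),
        (Bone.RADIUS, MeasurementType.DISTAL_BREADTH),
    }
)

#: Typical adult measurement values (mm) used by the registry sanity check.
DEFAULT_REFERENCE_INPUTS: dict[MeasurementKey, float] = {
    (Bone.HUMERUS, MeasurementType.LENGTH): 320.0,
    (Bone.HUMERUS, MeasurementType.PROXIMAL_BREADTH): 45.0,
    (Bone.HUMERUS, MeasurementType.MIDSHAFT_BREADTH): 22.0,
    (Bone.HUMERUS, MeasurementType.DISTAL_BREADTH): 60.0,
    (Bone.RADIUS, MeasurementType.LENGTH): 240.0,
    (Bone.RADIUS, MeasurementType.PROXIMAL_BREADTH): 22.0,
    (Bone.RADIUS, MeasurementType.MIDSHAFT_BREADTH): 15.0,
    (Bone.RADIUS, MeasurementType.DISTAL_BREADTH): 32.0,
    (Bone.ULNA, MeasurementType.LENGTH): 260.0,
    (Bone.ULNA, MeasurementType.MIDSHAFT_BREADTH): 14.0,
    (Bone.FEMUR, MeasurementType.LENGTH): 450.0,
    (Bone.FEMUR, MeasurementType.MIDSHAFT_BREADTH): 27.0,
    (Bone.FEMUR, MeasurementType.DISTAL_BREADTH): 80.0,
    (Bone.TIBIA, MeasurementType.LENGTH): 370.0,
    (Bone.TIBIA, MeasurementType.PROXIMAL_BREADTH): 72.0,
    (Bone.TIBIA, MeasurementType.MIDSHAFT_BREADTH): 25.0,
    (Bone.TIBIA, MeasurementType.DISTAL_BREADTH): 50.0,
    (Bone.FIBULA, MeasurementType.LENGTH): 360.0,
    (Bone.UPPER_LIMB, MeasurementType.LENGTH): 560.0,
    (Bone.LOWER_LIMB, MeasurementType.LENGTH): 820.0,
}

_SANITY_BAND_CM = (140.0, 200.0)


def _registry_bytes() -> bytes:
    try:
        return (
            resources.files("substature").joinpath("data", _REGISTRY_RESOURCE).read_bytes()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise RegistryIntegrityError("embedded registry asset missing") from exc


def load_registry() -> list[RegistryEntry]:
    """Load the 38 published models from the embedded, checksummed asset."""
    raw = _registry_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REGISTRY_SHA256:
        raise RegistryIntegrityError(
            f"registry checksum mismatch: expected {REGISTRY_SHA256}, got {digest}"
        )
    payload = json.loads(raw.decode("utf-8"))
    entries: list[RegistryEntry] = []
    for item in payload["models"]:
        spec = ModelSpec(
            bone=Bone(item["bone"]),
            measurement_type=MeasurementType(item["measurement"]),
            family=ModelFamily(item["family"]),
            coefficients=dict(item["coefficients"]),
        )
        entries.append(
            RegistryEntry(
                spec=spec,
                printed_metrics=dict(item.get("printed_metrics", {})),
                sanity_flag=bool(item.get("sanity_flag", False)),
            )
        )
    if len(entries) != 38:
        raise RegistryIntegrityError(f"registry must hold 38 models, found {len(entries)}")
    return entries


def registry_lookup(
    registry: list[RegistryEntry],
    bone: Bone,
    measurement_type: MeasurementType,
    family: ModelFamily,
) -> Optional[RegistryEntry]:
    for entry in registry:
        if entry.spec.key == (bone, measurement_type, family):
            return entry
    return None


def registry_sanity_check(
    reference_inputs: Optional[Mapping[MeasurementKey, float]] = None,
    registry: Optional[list[RegistryEntry]] = None,
) -> list[RegistryEntry]:
    """Flag registry entries that predict implausible adult statures.

    Each entry is evaluated at a typical adult value of its measurement;
    entries predicting outside [140, 200] cm get ``sanity_flag=True``.
    Returns the flagged entries (flags are also set in place).
    """
    if reference_inputs is None:
        reference_inputs = DEFAULT_REFERENCE_INPUTS
    if registry is None:
        registry = load_registry()
    missing = VALID_MEASUREMENTS - set(reference_inputs)
    if missing:
        raise ValueError(f"reference inputs missing measurements: {sorted(missing)}")
    flagged = []
    lo, hi = _SANITY_BAND_CM
    for entry in registry:
        x_ref = reference_inputs[(entry.spec.bone, entry.spec.measurement_type)]
        y_ref = evaluate_model(entry.spec, x_ref)
        entry.sanity_flag = not (lo <= y_ref <= hi)
        if entry.sanity_flag:
            flagged.append(entry)
    return flagged
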