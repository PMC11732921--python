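"""Cohort CSV format, model JSON serialization, and case reports.

The cohort table is a plain UTF-8 CSV (period decimal separator regardless
of locale) with columns ``id, sex, age_years, stature_cm`` followed by
measurement columns named ``<bone>_<measurement>_mm`` from the canonical
dictionary, and optional ``<bone>_<measurement>_kind`` columns with values
``diaphyseal`` or ``maximum``.  Empty cells mean missing.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .model_core import (
    VALID_MEASUREMENTS,
    Bone,
    FittedModel,
    MeasurementKey,
    MeasurementRecord,
    MeasurementType,
    ModelFamily,
    ModelSpec,
    REGISTRY_VERSION,
)
from .fitting import FitResult
from .prediction import PredictionResult

__all__ = [
    "MEASUREMENT_COLUMNS",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_models_json",
    "read_models_json",
    "case_report_json",
    "case_report_markdown",
]

#: Canonical column name per measurement, in the cohort-table order.
MEASUREMENT_COLUMNS: dict[str, MeasurementKey] = {
    f"{bone.value}_{mtype.value}_mm": (bone, mtype)
    for bone, mtype in sorted(VALID_MEASUREMENTS, key=lambda k: (k[0].value, k[1].value))
}
_KIND_COLUMNS = {name.replace("_mm", "_kind"): key for name, key in MEASUREMENT_COLUMNS.items()}
_META_COLUMNS = ("id", "sex", "age_years", "stature_cm")


class CohortValidationError(ValueError):
    """Cohort file failed validation; carries per-row error messages."""

    def __init__(self, message: str, row_errors: Optional[list[str]] = None):
        super().__init__(message)
        self.row_errors = row_errors or []


def read_cohort(path) -> list[MeasurementRecord]:
    """Read and validate a cohort CSV.

    Per-row problems are collected and reported with row numbers; the read
    fails outright when a required column is missing, an unknown column is
    present, or more than 10% of rows are invalid.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str, "sex": str})
    if "id" not in frame.columns:
        raise CohortValidationError("cohort file has no 'id' column")
    known = set(_META_COLUMNS) | set(MEASUREMENT_COLUMNS) | set(_KIND_COLUMNS)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise CohortValidationError(
            f"unknown columns: {', '.join(unknown)}; "
            f"measurement columns must come from the canonical dictionary"
        )
    records: list[MeasurementRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        rowno = idx + 2  # 1-based plus header line
        try:
            records.append(_row_to_record(row, rowno))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors and len(errors) > 0.10 * len(frame):
        raise CohortValidationError(
            f"{len(errors)} of {len(frame)} rows invalid (>10%)", errors
        )
    for msg in errors:
        import logging

        logging.getLogger(__name__).warning("dropped %s", msg)
    return records


def _row_to_record(row: pd.Series, rowno: int) -> MeasurementRecord:
    rid = row.get("id")
    if rid is None or (isinstance(rid, float) and np.isnan(rid)) or str(rid).strip() == "":
        raise ValueError("missing id")
    sex = row.get("sex", "unknown")
    if not isinstance(sex, str) or sex.strip() == "" or (isinstance(sex, float) and np.isnan(sex)):
        sex = "unknown"
    age = row.get("age_years")
    age = None if age is None or pd.isna(age) else float(age)
    stature = row.get("stature_cm")
    stature = None if stature is None or pd.isna(stature) else float(stature)
    measurements: dict[MeasurementKey, float] = {}
    kinds: dict[MeasurementKey, str] = {}
    for col, key in MEASUREMENT_COLUMNS.items():
        if col in row.index and not pd.isna(row[col]):
            value = float(row[col])
            if value <= 0:
                raise ValueError(f"column {col}: non-positive measurement {value}")
            measurements[key] = value
    for col, key in _KIND_COLUMNS.items():
        if col in row.index and isinstance(row[col], str) and row[col].strip():
            kinds[key] = row[col].strip()
    return MeasurementRecord(
        id=str(rid), sex=sex.strip(), age_years=age,
        known_stature_cm=stature, measurements=measurements,
        measurement_kind=kinds,
    )


def write_cohort(records: Sequence[MeasurementRecord], path) -> None:
    """Write records to the canonical cohort CSV (full float precision)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id,
            "sex": r.sex,
            "age_years": r.age_years,
            "stature_cm": r.known_stature_cm,
        }
        for col, key in MEASUREMENT_COLUMNS.items():
            if key in r.measurements:
                row[col] = repr(r.measurements[key])
        for col, key in _KIND_COLUMNS.items():
            if key in r.measurement_kind:
                row[col] = r.measurement_kind[key]
        rows.append(row)
    frame = pd.DataFrame(rows)
    # drop all-empty optional columns, keep canonical order
    order = [c for c in ("id", "sex", "age_years", "stature_cm") if c in frame.columns]
    order += [c for c in MEASUREMENT_COLUMNS if c in frame.columns]
    order += [c for c in _KIND_COLUMNS if c in frame.columns]
    frame = frame[order]
    frame.to_csv(path, index=False, float_format=None)


# ---------------------------------------------------------------------------
# Fitted-model serialization (same schema as the registry, plus fit fields)
# ---------------------------------------------------------------------------

def _model_to_dict(result: FitResult) -> dict:
    model = result.model
    out: dict = {
        "converged": result.converged,
        "iterations": result.iterations,
        "objective": result.objective,
        "message": result.message,
    }
    if model is None:
        return out
    out.update(
        {
            "bone": model.spec.bone.value,
            "measurement": model.spec.measurement_type.value,
            "family": model.spec.family.value,
            "coefficients": {k: float(v) for k, v in model.spec.coefficients.items()},
            "n": model.n,
            "residual_sd_cm": model.residual_sd,
            "x_mean": model.x_mean,
            "sxx": model.sxx,
            "x_min": model.x_min,
            "x_max": model.x_max,
            "param_covariance": (
                None if model.param_covariance is None
                else np.asarray(model.param_covariance).tolist()
            ),
        }
    )
    return out


def write_models_json(results: dict, path) -> None:
    """Serialize a fit_all result map to JSON."""
    payload = {
        "artifact_version": _pkg_version,
        "models": [_model_to_dict(res) for res in results.values()],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_models_json(path) -> dict:
    """Load fitted models back into a {key: FitResult} map."""
    payload = json.loads(Path(path).read_text())
    results = {}
    for item in payload["models"]:
        if "bone" not in item:
            continue
        spec = ModelSpec(
            Bone(item["bone"]),
            MeasurementType(item["measurement"]),
            ModelFamily(item["family"]),
            dict(item["coefficients"]),
        )
        cov = item.get("param_covariance")
        model = FittedModel(
            spec=spec,
            n=int(item["n"]),
            residual_sd=float(item["residual_sd_cm"]),
            converged=bool(item["converged"]),
            x_mean=item.get("x_mean"),
            sxx=item.get("sxx"),
            param_covariance=None if cov is None else np.asarray(cov, dtype=float),
            x_min=item.get("x_min"),
            x_max=item.get("x_max"),
        )
        results[spec.key] = FitResult(
            model=model,
            iterations=int(item.get("iterations", 0)),
            objective=float(item.get("objective", 0.0)),
            converged=bool(item["converged"]),
            message=item.get("message", ""),
        )
    return results


# ---------------------------------------------------------------------------
# Case report
# ---------------------------------------------------------------------------

def _result_to_dict(r: PredictionResult) -> dict:
    bone, mtype, family = r.model_id
    return {
        "bone": bone.value,
        "measurement": mtype.value,
        "family": family.value,
        "x_mm": r.x,
        "point_cm": round(r.point_cm, 1),
        "pi_lower_cm": round(r.pi_lower_cm, 1),
        "pi_upper_cm": round(r.pi_upper_cm, 1),
        "level": r.level,
        "method": r.method,
        "warnings": list(r.warnings),
    }


def case_report_json(
    record: MeasurementRecord,
    results: Sequence[PredictionResult],
    timestamp: Optional[str] = None,
) -> dict:
    """Structured case record: input echo, per-measurement estimates,
    warnings, and version stamps.  Point and bounds are rounded to 0.1 cm."""
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return {
        "artifact_version": _pkg_version,
        "registry_version": REGISTRY_VERSION,
        "timestamp": timestamp,
        "input": {
            "id": record.id,
            "sex": record.sex,
            "age_years": record.age_years,
            "known_stature_cm": record.known_stature_cm,
            "measurements_mm": {
                f"{k[0].value}_{k[1].value}": v for k, v in sorted(
                    record.measurements.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
                )
            },
        },
        "estimates": [_result_to_dict(r) for r in results],
        "warnings": sorted({w for r in results for w in r.warnings}),
    }


def case_report_markdown(report: dict) -> str:
    """Human-readable mirror of the JSON case report (deterministic)."""
    lines = [
        f"# Stature estimation case report — {report['input']['id']}",
        "",
        f"- artifact version: {report['artifact_version']}",
        f"- registry version: {report['registry_version']}",
        f"- generated: {report['timestamp']}",
        "",
        "## Input measurements (mm)",
        "",
    ]
    for name, value in report["input"]["measurements_mm"].items():
        lines.append(f"- {name}: {value:g}")
    lines += ["", "## Estimates (cm)", "",
              "| model | x (mm) | point | PI lower | PI upper | method |",
              "|---|---|---|---|---|---|"]
    for e in report["estimates"]:
        lines.append(
            f"| {e['bone']}_{e['measurement']}~{e['family']} | {e['x_mm']:g} "
            f"| {e['point_cm']} | {e['pi_lower_cm']} | {e['pi_upper_cm']} "
            f"| {e['method']} |"
        )
    if report["warnings"]:
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in report["warnings"]]
    return "\n".join(lines) + "\n"
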