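"""Validation battery: split, precision, distributional fit, agreement,
correlation, coverage, and misclassification tabulation.

A "misclassification" is a hold-out individual whose known stature falls
outside the model's 95% prediction interval; test accuracy is the
complementary percentage.  Distributional fit compares known and predicted
stature with the two-sample Kolmogorov–Smirnov statistic, precision with
the mean absolute deviation, and agreement with Bland–Altman limits
(bias ± 1.96·sd of the differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    Bone,
    FittedModel,
    MeasurementRecord,
    MeasurementType,
    ModelFamily,
    composite_lengths,
)
from .fitting import FitResult
from .prediction import PredictionResult, prediction_interval

__all__ = [
    "EvaluationReport",
    "PredictionOutcome",
    "train_test_split",
    "mean_absolute_deviation",
    "ks_two_sample",
    "test_accuracy",
    "bland_altman",
    "kendall_tau",
    "collect_predictions",
    "evaluate_models",
    "misclassification_report",
    "MisclassificationReport",
]

MIN_TEST_PAIRS = 5


@dataclass
class EvaluationReport:
    """Per-model metric bundle for a hold-out evaluation."""

    model_id: tuple[Bone, MeasurementType, ModelFamily]
    n_test: int
    kendall_tau: Optional[float] = None
    residual_sd_cm: Optional[float] = None
    ks_D: Optional[float] = None
    ks_p: Optional[float] = None
    test_accuracy_pct: Optional[float] = None
    mad_cm: Optional[float] = None
    bland_altman: Optional[dict[str, float]] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        bone, mtype, family = self.model_id
        return f"{bone.value}_{mtype.value}~{family.value}"


@dataclass
class PredictionOutcome:
    """One hold-out prediction, with the coverage verdict attached."""

    record_id: str
    model_id: tuple[Bone, MeasurementType, ModelFamily]
    x: float
    predicted_cm: float
    known_cm: float
    pi_lower_cm: float
    pi_upper_cm: float
    inside: bool


def train_test_split(
    records: Sequence[MeasurementRecord],
    train_frac: float = 0.8,
    seed: Optional[int] = None,
) -> tuple[list[MeasurementRecord], list[MeasurementRecord]]:
    """Seeded random partition into training and hold-out sets.

    Training size is round(n * train_frac); the split is disjoint and
    exhaustive, and the same seed reproduces the same membership.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    if seed is None:
        raise ValueError("a seed is required for a reproducible split")
    n = len(records)
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    n_train = int(round(n * train_frac))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [records[i] for i in sorted(perm[:n_train])]
    test = [records[i] for i in sorted(perm[n_train:])]
    return train, test


def mean_absolute_deviation(predicted: Sequence[float], known: Sequence[float]) -> float:
    """Mean of |predicted - known| in cm."""
    predicted = np.asarray(predicted, dtype=float)
    known = np.asarray(known, dtype=float)
    if predicted.shape != known.shape or predicted.size == 0:
        raise ValueError("predicted and known must be equal-length, nonempty")
    return float(np.mean(np.abs(predicted - known)))


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic D and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def test_accuracy(results: Sequence[PredictionResult | PredictionOutcome],
                  known: Optional[Sequence[float]] = None) -> float:
    """Percent of cases whose known stature lies inside the interval.

    Accepts either :class:`PredictionOutcome` rows (known stature embedded)
    or :class:`PredictionResult` plus a parallel ``known`` vector; results
    with an unavailable interval are excluded.
    """
    hits = 0
    total = 0
    for i, r in enumerate(results):
        if isinstance(r, PredictionOutcome):
            lo, hi, y = r.pi_lower_cm, r.pi_upper_cm, r.known_cm
        else:
            if r.method == "unavailable":
                continue
            if known is None:
                raise ValueError("known statures required with PredictionResult input")
            lo, hi, y = r.pi_lower_cm, r.pi_upper_cm, float(known[i])
        total += 1
        hits += int(lo <= y <= hi)
    if total == 0:
        raise ValueError("no usable results")
    return round(100.0 * hits / total, 1)


def bland_altman(predicted: Sequence[float], known: Sequence[float]) -> dict[str, float]:
    """Bland–Altman agreement: bias and bias ± 1.96·sd limits (cm)."""
    predicted = np.asarray(predicted, dtype=float)
    known = np.asarray(known, dtype=float)
    if predicted.shape != known.shape or predicted.size < 2:
        raise ValueError("need at least 2 paired values")
    d = predicted - known
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias_cm": bias,
        "lower_limit_cm": bias - 1.96 * sd,
        "upper_limit_cm": bias + 1.96 * sd,
    }


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined when either variable is all tied")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


def _usable_models(fitted) -> list[FittedModel]:
    models = []
    for value in (fitted.values() if isinstance(fitted, dict) else fitted):
        model = value.model if isinstance(value, FitResult) else value
        if model is not None and model.converged:
            models.append(model)
    return models


def collect_predictions(
    fitted,
    test_records: Sequence[MeasurementRecord],
    level: float = 0.95,
) -> list[PredictionOutcome]:
    """Hold-out predictions for every converged model, complete-case."""
    records = [composite_lengths(r) for r in test_records]
    records = [r for r in records if r.known_stature_cm is not None]
    outcomes: list[PredictionOutcome] = []
    for model in _usable_models(fitted):
        mkey = (model.spec.bone, model.spec.measurement_type)
        for rec in records:
            if mkey not in rec.measurements:
                continue
            pr = prediction_interval(model, rec.measurements[mkey], level)
            if pr.method == "unavailable":
                continue
            y = rec.known_stature_cm
            outcomes.append(
                PredictionOutcome(
                    record_id=rec.id,
                    model_id=model.spec.key,
                    x=pr.x,
                    predicted_cm=pr.point_cm,
                    known_cm=y,
                    pi_lower_cm=pr.pi_lower_cm,
                    pi_upper_cm=pr.pi_upper_cm,
                    inside=bool(pr.pi_lower_cm <= y <= pr.pi_upper_cm),
                )
            )
    return outcomes


def evaluate_models(
    fitted,
    test_records: Sequence[MeasurementRecord],
    level: float = 0.95,
) -> list[EvaluationReport]:
    """One report row per converged model, mirroring the published table
    columns: tau, residual SD, KS D (+p), test accuracy, MAD, Bland–Altman.
    """
    outcomes = collect_predictions(fitted, test_records, level)
    reports: list[EvaluationReport] = []
    for model in _usable_models(fitted):
        rows = [o for o in outcomes if o.model_id == model.spec.key]
        report = EvaluationReport(model_id=model.spec.key, n_test=len(rows),
                                  residual_sd_cm=model.residual_sd)
        if len(rows) < MIN_TEST_PAIRS:
            report.warnings.append(
                f"only {len(rows)} usable test pairs (< {MIN_TEST_PAIRS}); metrics withheld"
            )
            reports.append(report)
            continue
        pred = np.array([o.predicted_cm for o in rows])
        known = np.array([o.known_cm for o in rows])
        xs = np.array([o.x for o in rows])
        try:
            report.kendall_tau = kendall_tau(xs, known)
        except ValueError as exc:
            report.warnings.append(f"tau unavailable: {exc}")
        d, p = ks_two_sample(known, pred)
        report.ks_D, report.ks_p = d, p
        report.mad_cm = mean_absolute_deviation(pred, known)
        report.test_accuracy_pct = test_accuracy(rows)
        report.bland_altman = bland_altman(pred, known)
        reports.append(report)
    return reports


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Flatten evaluation reports to the published-table column layout."""
    rows = []
    for r in reports:
        bone, mtype, family = r.model_id
        ba = r.bland_altman or {}
        rows.append(
            {
                "bone": bone.value,
                "measurement": mtype.value,
                "family": family.value,
                "kendall_tau": r.kendall_tau,
                "residual_sd_cm": r.residual_sd_cm,
                "ks_D": r.ks_D,
                "ks_p": r.ks_p,
                "test_accuracy_pct": r.test_accuracy_pct,
                "mad_cm": r.mad_cm,
                "bias_cm": ba.get("bias_cm"),
                "loa_lower_cm": ba.get("lower_limit_cm"),
                "loa_upper_cm": ba.get("upper_limit_cm"),
                "n_test": r.n_test,
                "warnings": "; ".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MisclassificationReport:
    """Cross-tabulation of inaccurate predictions.

    ``pct_of_all`` cells are percentages among all predictions;
    ``pct_of_missed`` cells are percentages among misclassifications only.
    Both tables carry family rows, measurement-type columns, and marginal
    totals.
    """

    n_predictions: int
    n_misclassified: int
    overall_rate_pct: float
    pct_of_all: pd.DataFrame
    pct_of_missed: pd.DataFrame
    n_individuals_with_miss: int


_FAMILY_GROUP = {
    ModelFamily.LINEAR: "linear",
    ModelFamily.ASYMPTOTIC_EXPONENTIAL: "nonlinear",
    ModelFamily.LOGISTIC3: "nonlinear",
}
_MTYPE_ORDER = ["length", "proximal_breadth", "midshaft_breadth", "distal_breadth"]


def misclassification_report(
    outcomes: Sequence[PredictionOutcome],
) -> MisclassificationReport:
    """Tabulate misclassifications by model family and measurement type.

    Each cell reports two percentages: the share among all predictions and
    the share among misclassifications only; marginal totals are included,
    along with the number of individuals with at least one misclassification.
    """
    n_total = len(outcomes)
    missed = [o for o in outcomes if not o.inside]
    n_miss = len(missed)

    index = ["linear", "nonlinear", "total"]
    columns = _MTYPE_ORDER + ["total"]
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=float)
    for o in missed:
        fam = _FAMILY_GROUP[o.model_id[2]]
        mtype = o.model_id[1].value
        counts.loc[fam, mtype] += 1
    counts.loc["total"] = counts.loc[["linear", "nonlinear"]].sum()
    counts["total"] = counts[_MTYPE_ORDER].sum(axis=1)

    pct_all = 100.0 * counts / n_total if n_total else counts * np.nan
    pct_missed = 100.0 * counts / n_miss if n_miss else counts * 0.0
    rate = round(100.0 * n_miss / n_total, 2) if n_total else float("nan")
    individuals = len({o.record_id for o in missed})
    return MisclassificationReport(
        n_predictions=n_total,
        n_misclassified=n_miss,
        overall_rate_pct=rate,
        pct_of_all=pct_all,
        pct_of_missed=pct_missed,
        n_individuals_with_miss=individuals,
    )
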