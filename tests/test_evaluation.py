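"""Validation metrics against brute-force oracles and hand arithmetic."""

import numpy as np
import pytest

from substature import (
    Bone,
    MeasurementType,
    ModelFamily,
    bland_altman,
    evaluate_models,
    kendall_tau,
    ks_two_sample,
    mean_absolute_deviation,
    misclassification_report,
    train_test_split,
)
from substature import test_accuracy as coverage_accuracy
from substature.evaluation import PredictionOutcome

L, A, G = ModelFamily.LINEAR, ModelFamily.ASYMPTOTIC_EXPONENTIAL, ModelFamily.LOGISTIC3


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_ks(a, b):
    """sup_t |Fa(t) - Fb(t)| by checking every data breakpoint."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return best


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestSplit:
    def test_sizes_and_disjointness(self, cohort):
        train, test = train_test_split(cohort[:10], 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2
        assert {r.id for r in train}.isdisjoint({r.id for r in test})

    def test_determinism(self, cohort):
        a = train_test_split(cohort, 0.8, seed=9)
        b = train_test_split(cohort, 0.8, seed=9)
        assert [r.id for r in a[0]] == [r.id for r in b[0]]
        assert [r.id for r in a[1]] == [r.id for r in b[1]]

    def test_990_individuals_split_792_198(self):
        from substature import MeasurementRecord

        records = [MeasurementRecord(id=f"r{i}") for i in range(990)]
        train, test = train_test_split(records, 0.8, seed=4)
        assert (len(train), len(test)) == (792, 198)

    def test_too_small_rejected(self, cohort):
        with pytest.raises(ValueError):
            train_test_split(cohort[:4], 0.8, seed=1)


class TestMAD:
    @pytest.mark.parametrize(
        "pred,known,expected",
        [([1, 2, 3], [1, 2, 3], 0.0), ([100, 110], [102, 106], 3.0), ([105], [100], 5.0)],
    )
    def test_examples(self, pred, known, expected):
        assert mean_absolute_deviation(pred, known) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mean_absolute_deviation([1, 2], [1])

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p, k = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        assert mean_absolute_deviation(p, k) == pytest.approx(
            mean_absolute_deviation(p[perm], k[perm])
        )


class TestKS:
    @pytest.mark.parametrize(
        "a,b,expected",
        [([1, 2, 3], [1, 2, 3], 0.0), ([1, 2], [3, 4], 1.0), ([1, 2], [1.5, 2.5], 0.5)],
    )
    def test_examples(self, a, b, expected):
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(expected)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            na, nb = rng.integers(2, 50, size=2)
            a = rng.normal(size=na)
            b = rng.normal(0.3, 1.2, size=nb)
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestKendallTau:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),
            ([1, 2, 3], [1, 3, 2], 1 / 3),
        ],
    )
    def test_examples(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected)

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = rng.integers(3, 100)
            x = rng.integers(0, 10, size=n).astype(float)  # ties guaranteed
            y = rng.integers(0, 10, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert kendall_tau(x, y) == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestAccuracyAndBlandAltman:
    def _outcome(self, inside, rid="r", fam=L, mtype=MeasurementType.LENGTH):
        lo, hi = (0.0, 200.0) if inside else (0.0, 10.0)
        return PredictionOutcome(
            record_id=rid, model_id=(Bone.HUMERUS, mtype, fam), x=100.0,
            predicted_cm=100.0, known_cm=100.0, pi_lower_cm=lo, pi_upper_cm=hi,
            inside=inside,
        )

    def test_accuracy_examples(self):
        all_in = [self._outcome(True) for _ in range(4)]
        assert coverage_accuracy(all_in) == 100.0
        none_in = [self._outcome(False) for _ in range(4)]
        assert coverage_accuracy(none_in) == 0.0
        three_of_four = [self._outcome(True)] * 3 + [self._outcome(False)]
        assert coverage_accuracy(three_of_four) == 75.0

    @pytest.mark.parametrize(
        "pred,known,bias,lower,upper",
        [
            ([5, 7], [5, 7], 0.0, 0.0, 0.0),
            ([1, -1], [0, 0], 0.0, -1.96 * np.sqrt(2), 1.96 * np.sqrt(2)),
            ([12, 22], [10, 20], 2.0, 2.0, 2.0),
        ],
    )
    def test_bland_altman_examples(self, pred, known, bias, lower, upper):
        out = bland_altman(pred, known)
        assert out["bias_cm"] == pytest.approx(bias, abs=1e-12)
        assert out["lower_limit_cm"] == pytest.approx(lower, abs=1e-9)
        assert out["upper_limit_cm"] == pytest.approx(upper, abs=1e-9)

    def test_bland_altman_needs_two(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestEvaluateModels:
    def test_one_report_per_converged_model(self, fitted, split):
        _, test = split
        reports = evaluate_models(fitted, test)
        n_conv = sum(1 for r in fitted.values() if r.converged)
        assert len(reports) == n_conv

    def test_metrics_finite_and_in_range(self, fitted, split):
        _, test = split
        for r in evaluate_models(fitted, test):
            if r.test_accuracy_pct is None:
                continue
            assert 0 <= r.test_accuracy_pct <= 100
            assert -1 <= r.kendall_tau <= 1
            assert 0 <= r.ks_D <= 1
            assert r.mad_cm >= 0
            ba = r.bland_altman
            assert ba["lower_limit_cm"] <= ba["bias_cm"] <= ba["upper_limit_cm"]


class TestMisclassification:
    def _outcomes(self, spec_counts):
        """spec_counts: {(family, mtype): (n_total, n_missed)}"""
        out = []
        i = 0
        for (fam, mtype), (n_tot, n_miss) in spec_counts.items():
            for j in range(n_tot):
                inside = j >= n_miss
                out.append(
                    PredictionOutcome(
                        record_id=f"id{i % 197}",
                        model_id=(Bone.HUMERUS, mtype, fam),
                        x=1.0, predicted_cm=100.0, known_cm=100.0,
                        pi_lower_cm=0.0,
                        pi_upper_cm=200.0 if inside else 50.0,
                        inside=inside,
                    )
                )
                i += 1
        return out

    def test_zero_misclassifications(self):
        outcomes = self._outcomes({(L, MeasurementType.LENGTH): (10, 0)})
        rep = misclassification_report(outcomes)
        assert rep.n_misclassified == 0
        assert rep.n_individuals_with_miss == 0
        assert (rep.pct_of_all.loc[["linear", "nonlinear"]].to_numpy() == 0).all()

    def test_published_overall_rate_arithmetic(self):
        """296 misclassified of 6675 predictions gives a 4.43% rate and a
        49.0% linear share of the misclassifications."""
        mt = MeasurementType
        # per-cell (total, missed) counts reconstructed from the published
        # percent-of-all cells: pct * 6675 / 100, rounded
        cells = {
            (L, mt.LENGTH): 52, (L, mt.PROXIMAL_BREADTH): 13,
            (L, mt.MIDSHAFT_BREADTH): 39, (L, mt.DISTAL_BREADTH): 41,
            (A, mt.LENGTH): 39, (G, mt.PROXIMAL_BREADTH): 33,
            (G, mt.MIDSHAFT_BREADTH): 48, (G, mt.DISTAL_BREADTH): 31,
        }
        assert sum(cells.values()) == 296
        per_cell_totals = 6675 // len(cells)
        spec_counts = {}
        rem = 6675
        for k, miss in cells.items():
            tot = per_cell_totals if len(spec_counts) < len(cells) - 1 else rem
            spec_counts[k] = (tot, miss)
            rem -= tot
        outcomes = self._outcomes(spec_counts)
        rep = misclassification_report(outcomes)
        assert rep.n_predictions == 6675
        assert rep.n_misclassified == 296
        assert rep.overall_rate_pct == pytest.approx(4.43, abs=0.005)
        linear_share = rep.pct_of_missed.loc["linear", "total"]
        assert linear_share == pytest.approx(49.0, abs=0.05)
        nonlinear_share = rep.pct_of_missed.loc["nonlinear", "total"]
        assert nonlinear_share == pytest.approx(51.0, abs=0.05)

    def test_cell_percentages_sum_correctly(self, fitted, split):
        """Percent-of-all cells sum to the overall rate; percent-of-missed
        cells sum to 100."""
        from substature import collect_predictions

        _, test = split
        outcomes = collect_predictions(fitted, test)
        rep = misclassification_report(outcomes)
        cells = rep.pct_of_all.loc[["linear", "nonlinear"],
                                   ["length", "proximal_breadth",
                                    "midshaft_breadth", "distal_breadth"]]
        assert cells.to_numpy().sum() == pytest.approx(
            100.0 * rep.n_misclassified / rep.n_predictions, abs=1e-9
        )
        if rep.n_misclassified:
            missed_cells = rep.pct_of_missed.loc[
                ["linear", "nonlinear"],
                ["length", "proximal_breadth", "midshaft_breadth", "distal_breadth"],
            ]
            assert missed_cells.to_numpy().sum() == pytest.approx(100.0, abs=1e-9)
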