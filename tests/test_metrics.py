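"""Accuracy measures, confidence intervals, ROC/AUC, and the
summary-to-confusion-matrix reconstruction oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microcyte.cohort import BTT, IDA
from microcyte.metrics import (
    ConfusionMatrix,
    ReconstructionError,
    compare_auc,
    confusion,
    empirical_auc,
    metric_cis,
    metric_set,
    recover_confusion_from_summary,
)


def brute_force_recover(youden, accuracy, n_pos, n_neg):
    """Independent oracle: exhaustive search over integer (tp, tn)."""
    hits = []
    for tp in range(n_pos + 1):
        for tn in range(n_neg + 1):
            j = round(100 * (tp / n_pos + tn / n_neg - 1), 2)
            a = round(100 * (tp + tn) / (n_pos + n_neg), 2)
            if j == youden and a == accuracy:
                hits.append((tp, tn))
    return hits


class TestConfusion:
    def test_perfect_agreement(self):
        truth = [BTT] * 6 + [IDA] * 4
        cm = confusion(truth, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (6, 0, 0, 4)

    def test_all_predicted_positive(self):
        truth = [BTT] * 7 + [IDA] * 3
        cm = confusion(truth, [BTT] * 10)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (7, 3, 0, 0)

    def test_prediction_swap_symmetry(self):
        truth = [BTT, BTT, IDA, IDA, BTT]
        pred = [BTT, IDA, BTT, IDA, BTT]
        cm = confusion(truth, pred)
        flipped = confusion(truth, [IDA if p == BTT else BTT for p in pred])
        assert (flipped.tp, flipped.tn) == (cm.fn, cm.fp)

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            confusion([BTT, "??"], [BTT, IDA])


class TestMetricSet:
    def test_published_cart_guide_row(self):
        ms = metric_set(ConfusionMatrix(668, 60, 40, 410))
        assert round(ms.dor, 2) == 114.12
        assert round(100 * ms.youden, 2) == 81.58
        assert round(100 * ms.accuracy, 2) == 91.51
        assert round(100 * ms.f_measure, 2) == 93.04
        assert round(ms.auc, 3) == 0.908

    def test_perfect_classifier(self):
        ms = metric_set(ConfusionMatrix(708, 0, 0, 470))
        assert ms.sensitivity == ms.specificity == ms.accuracy == 1.0
        assert ms.nlr == 0.0
        assert math.isinf(ms.dor)

    def test_zero_false_negatives_infinity_convention(self):
        ms = metric_set(ConfusionMatrix(708, 398, 0, 72))
        assert ms.sensitivity == 1.0
        assert ms.nlr == 0.0
        assert math.isinf(ms.dor)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            metric_set(ConfusionMatrix(5, 0, 3, 0))

    @given(
        tp=st.integers(0, 80), fp=st.integers(0, 80),
        fn=st.integers(0, 80), tn=st.integers(0, 80),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_identity_chain(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        ms = metric_set(ConfusionMatrix(tp, fp, fn, tn))
        assert ms.fpr == pytest.approx(1 - ms.specificity)
        assert ms.fnr == pytest.approx(1 - ms.sensitivity)
        assert ms.youden == pytest.approx(ms.sensitivity + ms.specificity - 1)
        assert ms.auc == pytest.approx((ms.youden + 1) / 2)
        if fp and fn and tp and tn:
            assert ms.dor == pytest.approx(ms.plr / ms.nlr)
            assert ms.dor == pytest.approx(tp * tn / (fp * fn))


class TestConfidenceIntervals:
    def test_degenerate_sensitivity_lower_bound_zero(self):
        cis = metric_cis(ConfusionMatrix(0, 0, 10, 10), n_boot=200)
        assert cis["sensitivity"][0] == 0.0

    def test_dor_log_method_matches_published_scale(self):
        # hand calculation: ln(114.12) +/- 1.96*sqrt(1/668+1/60+1/40+1/410)
        cis = metric_cis(ConfusionMatrix(668, 60, 40, 410), n_boot=200)
        lo, hi = cis["dor"]
        assert lo == pytest.approx(75.09, abs=0.5)
        assert hi == pytest.approx(173.43, abs=0.5)

    def test_level_monotonicity(self):
        cm = ConfusionMatrix(668, 60, 40, 410)
        wide = metric_cis(cm, level=0.95, n_boot=500)
        narrow = metric_cis(cm, level=0.5, n_boot=500)
        for measure in ("sensitivity", "specificity", "dor", "youden"):
            assert (narrow[measure][1] - narrow[measure][0]) < (
                wide[measure][1] - wide[measure][0]
            )

    def test_proportion_cis_bracket_estimates(self):
        cm = ConfusionMatrix(668, 60, 40, 410)
        ms = metric_set(cm)
        cis = metric_cis(cm, n_boot=500)
        for measure in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lo, hi = cis[measure]
            assert lo <= getattr(ms, measure) <= hi


class TestEmpiricalAuc:
    def test_all_ties_give_half(self):
        truth = [BTT] * 5 + [IDA] * 5
        assert empirical_auc([1.0] * 10, truth).auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        truth = [BTT] * 5 + [IDA] * 5
        curve = empirical_auc([9, 8, 7, 6, 5, 4, 3, 2, 1, 0], truth)
        assert curve.auc == pytest.approx(1.0)

    def test_binary_scores_match_half_sens_plus_spec(self):
        # sens 0.9675, spec 0.9128 at the published class sizes -> AUC 0.940
        tp, fn = 685, 23
        tn, fp = 429, 41
        scores = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        truth = [BTT] * (tp + fn) + [IDA] * (fp + tn)
        curve = empirical_auc(scores, truth)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        assert curve.auc == pytest.approx((sens + spec) / 2)
        assert round(curve.auc, 3) == 0.940

    def test_direction_flip(self):
        rng = np.random.default_rng(3)
        truth = [BTT] * 50 + [IDA] * 50
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
        up = empirical_auc(scores, truth, "higher-is-BTT")
        down = empirical_auc(scores, truth, "lower-is-BTT")
        assert up.auc == pytest.approx(1 - down.auc)

    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(7)
        n_pos, n_neg = 60, 40
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force ties
        truth = [BTT] * n_pos + [IDA] * n_neg
        curve = empirical_auc(scores, truth)
        pos, neg = scores[:n_pos], scores[n_pos:]
        conc = sum(
            1.0 if p > q else 0.5 if p == q else 0.0
            for p, q in itertools.product(pos, neg)
        ) / (n_pos * n_neg)
        assert curve.auc == pytest.approx(conc, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            empirical_auc([1, 2, 3], [BTT, BTT, BTT])


class TestCompareAuc:
    def _curves(self):
        rng = np.random.default_rng(1)
        truth = [BTT] * 250 + [IDA] * 250
        strong = np.concatenate([rng.normal(3, 1, 250), rng.normal(0, 1, 250)])
        noise = rng.normal(0, 1, 500)
        return empirical_auc(strong, truth), empirical_auc(noise, truth)

    def test_curve_vs_itself(self):
        curve, _ = self._curves()
        z, p = compare_auc(curve, curve)
        assert z == 0.0 and p == 1.0

    def test_separated_vs_random_is_significant(self):
        strong, noise = self._curves()
        z, p = compare_auc(strong, noise)
        assert p < 0.001

    def test_antisymmetry(self):
        strong, noise = self._curves()
        z_ab, _ = compare_auc(strong, noise)
        z_ba, _ = compare_auc(noise, strong)
        assert z_ba == pytest.approx(-z_ab)

    def test_unpaired_inputs_error(self):
        strong, _ = self._curves()
        other = empirical_auc([1, 2, 3, 4], [BTT, BTT, IDA, IDA])
        with pytest.raises(ValueError):
            compare_auc(strong, other)


class TestRecoverConfusion:
    @pytest.mark.parametrize(
        ("youden", "accuracy", "expected"),
        [
            (81.58, 91.51, (668, 60, 40, 410)),  # published CART/GUIDE row
            (88.03, 94.57, (685, 41, 23, 429)),  # published CRUISE row
        ],
    )
    def test_published_rows(self, youden, accuracy, expected):
        cm = recover_confusion_from_summary(youden, accuracy, 708, 470)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected
        # cross-check with the exhaustive-search oracle
        assert brute_force_recover(youden, accuracy, 708, 470) == [
            (expected[0], expected[3])
        ]

    def test_perfect_classifier(self):
        cm = recover_confusion_from_summary(100.0, 100.0, 10, 5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 5)

    def test_inconsistent_inputs_error(self):
        with pytest.raises(ReconstructionError):
            recover_confusion_from_summary(95.0, 50.0, 708, 470)

    def test_equal_class_sizes_error(self):
        with pytest.raises(ReconstructionError):
            recover_confusion_from_summary(50.0, 75.0, 100, 100)

    @given(tp=st.integers(0, 708), tn=st.integers(0, 470))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_roundtrip_identity_at_study_sizes(self, tp, tn):
        """recover o metric_set is the identity on 2-dp (Youden, accuracy)."""
        n_pos, n_neg = 708, 470
        youden = round(100 * (tp / n_pos + tn / n_neg - 1), 2)
        accuracy = round(100 * (tp + tn) / (n_pos + n_neg), 2)
        cm = recover_confusion_from_summary(youden, accuracy, n_pos, n_neg)
        assert (cm.tp, cm.tn) == (tp, tn)
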