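"""Confusion metrics, ROC/AUC, and the four-fold chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from nodesphere.evaluation import (
    ConfusionCounts,
    chi2_fourfold,
    confusion_metrics,
    evaluate_method,
    roc_auc,
)
from tests.conftest import two_class_scores


def pairwise_auc(scores, labels):
    """Exhaustive concordance statistic: mean over (pos, neg) pairs of
    [s_pos > s_neg] + 0.5*[tie]."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_accuracy_arithmetic_examples(self):
        # 137 nodes, 19 errors -> 86.1%; 5 errors -> 96.4% (132/137)
        m19 = confusion_metrics(ConfusionCounts(tp=34, fp=16, tn=84, fn=3))
        assert m19.accuracy == pytest.approx(118 / 137)
        assert round(100 * m19.accuracy, 1) == 86.1
        m5 = confusion_metrics(ConfusionCounts(tp=35, fp=3, tn=97, fn=2))
        assert m5.accuracy == pytest.approx(132 / 137)

    def test_undefined_class_flagged_not_nan(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=2, tn=8, fn=0))
        assert m.sensitivity is None
        assert m.youden_j is None
        assert m.specificity == pytest.approx(0.8)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_roundtrip_from_rates(self):
        """Counts rebuilt from (sens, spec, class sizes) give back the
        same metrics for integer-consistent inputs."""
        counts = ConfusionCounts(tp=28, fp=11, tn=89, fn=9)
        m = confusion_metrics(counts)
        n_pos = counts.tp + counts.fn
        n_neg = counts.tn + counts.fp
        rebuilt = ConfusionCounts(
            tp=round(m.sensitivity * n_pos),
            fn=n_pos - round(m.sensitivity * n_pos),
            tn=round(m.specificity * n_neg),
            fp=n_neg - round(m.specificity * n_neg),
        )
        assert rebuilt == counts
        m2 = confusion_metrics(rebuilt)
        assert m2 == m


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = (rng.random(4000) < 0.3).astype(int)
        r = roc_auc(scores, labels)
        assert abs(r.auc - 0.5) < 0.03

    def test_trapezoid_equals_pairwise_oracle(self, rng):
        for trial in range(5):
            scores, labels = two_class_scores(rng, 40, 120)
            # inject ties
            scores = np.round(scores, 2)
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores, labels = two_class_scores(rng, 30, 70)
        r1 = roc_auc(scores, labels)
        r2 = roc_auc(np.exp(3 * scores), labels)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_sign_flip_complement(self, rng):
        scores, labels = two_class_scores(rng, 30, 70)
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_auto_orient_flips_and_warns(self, rng, caplog):
        scores, labels = two_class_scores(rng, 30, 70)
        with caplog.at_level("WARNING"):
            r = roc_auc(-scores, labels, auto_orient=True)
        assert r.flipped
        assert r.auc > 0.5


class TestChi2:
    def test_identical_methods(self):
        stat, p = chi2_fourfold(30, 10, 30, 10)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table, want_stat, want_p",
        [
            # closed-form hand computation on the implied comparison tables
            ((38, 5, 30, 13), 4.4967, 0.0340),
            ((39, 4, 30, 13), 5.9386, 0.0148),
        ],
    )
    def test_closed_form_values(self, table, want_stat, want_p):
        stat, p = chi2_fourfold(*table)
        assert stat == pytest.approx(want_stat, abs=5e-3)
        assert p == pytest.approx(want_p, abs=5e-4)

    def test_matches_scipy_contingency(self, rng):
        """Two independent implementations agree to 1e-10."""
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, size=4)
            stat, p = chi2_fourfold(int(a), int(b), int(c), int(d))
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            stat_y, p_y = chi2_fourfold(int(a), int(b), int(c), int(d),
                                        correction=True)
            ref_y = chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat_y == pytest.approx(ref_y.statistic, abs=1e-10)
            assert p_y == pytest.approx(ref_y.pvalue, abs=1e-10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi2_fourfold(0, 0, 30, 13)


class TestEvaluateMethod:
    def test_perfect_calls(self):
        df = pd.DataFrame({"call": [1, 0, 1], "truth": [1, 0, 1]})
        m, counts = evaluate_method(df)
        assert m.correct_classification_rate == 1.0
        assert counts.errors == 0

    def test_ultrasound_style_ccr(self):
        # 39 patients: 7 TP, 8 TN, 21 FN, 3 FP -> CCR 15/39 = 38.5%
        calls = [1] * 7 + [0] * 8 + [0] * 21 + [1] * 3
        truth = [1] * 7 + [0] * 8 + [1] * 21 + [0] * 3
        m, counts = evaluate_method(pd.DataFrame({"call": calls, "truth": truth}))
        assert counts.total == 39
        assert m.accuracy == pytest.approx(15 / 39)
        assert round(100 * m.accuracy, 1) == 38.5

    def test_nac_subgroup(self):
        # 11-patient subgroup with 3 errors -> CCR 8/11 = 72.7%
        df = pd.DataFrame(
            {
                "call": [1] * 4 + [0] * 4 + [0] * 2 + [1] + [1, 0],
                "truth": [1] * 4 + [0] * 4 + [1] * 2 + [0] + [1, 0],
                "nac": [1] * 11 + [0, 0],
            }
        )
        m, counts = evaluate_method(df, subgroup="nac")
        assert counts.total == 11
        assert m.accuracy == pytest.approx(8 / 11)
        assert round(100 * m.accuracy, 1) == 72.7

    def test_empty_subgroup_errors(self):
        df = pd.DataFrame({"call": [1], "truth": [1], "nac": [0]})
        with pytest.raises(ValueError):
            evaluate_method(df, subgroup="nac")
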