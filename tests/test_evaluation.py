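"""SE/SP/Q/MCC metrics, confusion tallies, ROC and comparison tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoreact.evaluation import (
    ConfusionCounts,
    EvalReport,
    comparison_table,
    confusion,
    evaluate,
    metrics_from_counts,
    roc_points,
    round2,
)


class TestMetricsFromCounts:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # published evaluation rows recomputed from their confusion counts
            ((441, 435, 62, 60), {"se": 0.88, "sp": 0.88, "q": 0.88, "mcc": 0.76}),
            ((391, 362, 138, 107), {"mcc": 0.51}),
            ((454, 432, 60, 52), {"q": 0.89}),
            ((460, 428, 64, 46), {"se": 0.91}),
            ((10, 10, 0, 0), {"se": 1.0, "sp": 1.0, "q": 1.0, "mcc": 1.0}),
        ],
    )
    def test_rounded_values(self, counts, expected):
        tp, tn, fp, fn = counts
        report = metrics_from_counts(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        for key, value in expected.items():
            assert report.rounded()[key] == value

    def test_undefined_mcc_flagged_zero(self):
        report = metrics_from_counts(ConfusionCounts(tp=5, tn=0, fp=5, fn=0))
        assert report.mcc == 0.0 and report.mcc_undefined

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_oracle_equivalence_random_quadruples(self):
        """Direct-formula oracle agreement to 1e-12 over 1000 random draws."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 500, 4))
            if tp + tn + fp + fn == 0:
                continue
            r = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
            if tp + fn:
                assert abs(r.se - tp / (tp + fn)) < 1e-12
            if tn + fp:
                assert abs(r.sp - tn / (tn + fp)) < 1e-12
            assert abs(r.q - (tp + tn) / (tp + tn + fp + fn)) < 1e-12
            denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
            if denom:
                assert abs(r.mcc - (tp * tn - fn * fp) / math.sqrt(denom)) < 1e-12

    def test_mcc_matches_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 40, 4))
            y_true = ["POS"] * (tp + fn) + ["NEG"] * (tn + fp)
            y_pred = ["POS"] * tp + ["NEG"] * fn + ["NEG"] * tn + ["POS"] * fp
            mine = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn)).mcc
            assert mine == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(counts=st.tuples(*[st.integers(0, 1000)] * 4))
    def test_mcc_label_swap_symmetry(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        a = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
        b = metrics_from_counts(ConfusionCounts(tn, tp, fn, fp))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(counts=st.tuples(*[st.integers(1, 1000)] * 4))
    def test_q_is_weighted_mean_of_se_sp(self, counts):
        tp, tn, fp, fn = counts
        r = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
        total = tp + tn + fp + fn
        assert r.q == pytest.approx(
            r.se * (tp + fn) / total + r.sp * (tn + fp) / total, abs=1e-12
        )


class TestConfusion:
    def test_all_pos_agreement(self):
        c = confusion(["POS"] * 4, ["POS"] * 4)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 0, 0, 0)

    def test_complement(self):
        c = confusion(["POS", "NEG"], ["NEG", "POS"])
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 1)

    def test_hand_tally(self):
        y_true = ["POS", "POS", "NEG", "NEG", "POS", "NEG"]
        y_pred = ["POS", "NEG", "NEG", "POS", "POS", "NEG"]
        c = confusion(y_true, y_pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["POS"], ["POS", "NEG"])


class TestRoc:
    def test_perfect_and_reversed(self):
        y = ["POS", "POS", "NEG", "NEG"]
        pts, auc = roc_points(y, [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0
        _, auc_rev = roc_points(y, [0.1, 0.2, 0.8, 0.9])
        assert auc_rev == 0.0

    def test_endpoints_and_monotone(self):
        rng = np.random.default_rng(5)
        y = ["POS" if v else "NEG" for v in rng.integers(0, 2, 50)]
        pts, _ = roc_points(y, rng.random(50))
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(7)
        y = ["POS" if v else "NEG" for v in rng.integers(0, 2, 2000)]
        _, auc = roc_points(y, rng.random(2000))
        assert abs(auc - 0.5) < 0.05

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_points(["POS", "POS"], [0.5, 0.6])


class TestComparisonTable:
    def _report(self, counts, oob=None):
        r = metrics_from_counts(ConfusionCounts(*counts))
        r.oob_accuracy = oob
        return r

    def test_sorted_by_mcc_then_q(self):
        table = comparison_table(
            {
                "weak": self._report((391, 362, 138, 107)),
                "strong": self._report((441, 435, 62, 60), oob=0.88),
            }
        )
        assert list(table["model"]) == ["strong", "weak"]
        assert table.loc[0, "q_tr"] == 0.88

    def test_tie_on_mcc_higher_q_first(self):
        # equal-MCC pair differing in Q: the higher-Q model leads
        a = self._report((50, 50, 10, 10))
        b = self._report((5, 5, 1, 1))
        assert a.mcc == pytest.approx(b.mcc)
        table = comparison_table({"b": b, "a": a})
        # identical MCC and Q: stable sort preserves insertion order
        assert list(table["model"]) == ["b", "a"]
        # true MCC tie (both 0) with different Q: higher Q leads
        hi_q = self._report((9, 1, 3, 3))
        lo_q = self._report((10, 10, 10, 10))
        mixed = comparison_table({"lo": lo_q, "hi": hi_q})
        assert list(mixed["model"]) == ["hi", "lo"]

    def test_single_and_empty(self):
        table = comparison_table({"only": self._report((1, 1, 1, 1))})
        assert len(table) == 1
        with pytest.raises(ValueError):
            comparison_table({})


class TestEvaluateWrapper:
    def test_full_report(self):
        y_true = ["POS", "POS", "NEG", "NEG"]
        y_pred = ["POS", "NEG", "NEG", "NEG"]
        scores = [0.9, 0.4, 0.2, 0.3]
        r = evaluate(y_true, y_pred, pos_scores=scores)
        assert r.counts.tp == 1 and r.counts.fn == 1
        assert r.auc is not None and r.roc[0] == (0.0, 0.0)

    def test_round_half_up(self):
        assert round2(0.875) == 0.88
        assert round2(0.125) == 0.13
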