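"""Confusion-count, Dice and Jaccard metric correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mammopt import metrics
from mammopt.metrics import (
    ConfusionCounts,
    classification_metrics,
    confusion_counts,
    dice,
    jaccard,
)

counts_st = st.tuples(*[st.integers(0, 200)] * 4).filter(lambda t: sum(t) > 0)


def brute_force(tp, fp, tn, fn, mode):
    """Independent per-definition computation of all ten metrics."""
    def r(num, den):
        return float("nan") if den == 0 else num / den

    out = {
        "accuracy": r(tp + tn, tp + fp + tn + fn),
        "precision": r(tp, tp + fp),
        "sensitivity": r(tp, tp + fn),
        "fdr": r(fp, fp + tp),
        "fnr": r(fn, fn + tp),
    }
    if mode == "as_printed":
        out["fpr"] = r(fp, fn + fp)
        out["npv"] = r(tn, fp + tn)
        out["specificity"] = r(tn, fn + tp)
        out["f1"] = r(2 * tp, 2 * (tp + fp + fn))
    else:
        out["fpr"] = r(fp, fp + tn)
        out["npv"] = r(tn, tn + fn)
        out["specificity"] = r(tn, tn + fp)
        out["f1"] = r(2 * tp, 2 * tp + fp + fn)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = float("nan") if den == 0 else (tp * tn - fp * fn) / den
    return out


def random_mask_pair(rng, shape=(16, 16)):
    return (rng.random(shape) < 0.3).astype(int), (rng.random(shape) < 0.3).astype(int)


class TestConfusionCounts:
    @pytest.mark.parametrize(
        "pred,truth,expect",
        [
            ([1, 1, 0, 0], [1, 0, 0, 1], (1, 1, 1, 1)),
            ([1, 0, 1], [1, 0, 1], (2, 0, 1, 0)),
        ],
    )
    def test_examples(self, pred, truth, expect):
        c = confusion_counts(pred, truth, positive_label=1)
        assert (c.tp, c.fp, c.tn, c.fn) == expect
        assert c.total == len(pred)

    def test_matches_per_element_loop_on_random_pairs(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, size=1000)
        truth = rng.integers(0, 2, size=1000)
        c = confusion_counts(pred, truth)
        tp = fp = tn = fn = 0
        for p, t in zip(pred, truth):
            if p == 1 and t == 1:
                tp += 1
            elif p == 1:
                fp += 1
            elif t == 1:
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion_counts([1], [1, 0])
        with pytest.raises(ValueError):
            confusion_counts([], [])
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestClassificationMetrics:
    def test_accuracy_example_both_modes(self):
        c = ConfusionCounts(tp=50, fp=5, tn=40, fn=5)
        for mode in ("standard", "as_printed"):
            assert classification_metrics(c, mode).accuracy == pytest.approx(0.90)

    def test_specificity_differs_between_modes(self):
        c = ConfusionCounts(tp=50, fp=5, tn=40, fn=5)
        assert classification_metrics(c, "standard").specificity == pytest.approx(40 / 45)
        assert classification_metrics(c, "as_printed").specificity == pytest.approx(40 / 55)

    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=7, fp=0, tn=4, fn=0)
        for mode in ("standard", "as_printed"):
            rep = classification_metrics(c, mode)
            assert rep.precision == rep.sensitivity == rep.accuracy == 1.0
            assert rep.mcc == 1.0

    @given(counts_st, st.sampled_from(["standard", "as_printed"]))
    def test_matches_brute_force(self, counts, mode):
        tp, fp, tn, fn = counts
        rep = classification_metrics(ConfusionCounts(tp, fp, tn, fn), mode).as_dict()
        expect = brute_force(tp, fp, tn, fn, mode)
        for key, want in expect.items():
            got = rep[key]
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    @given(counts_st, st.sampled_from(["standard", "as_printed"]))
    def test_complement_identities(self, counts, mode):
        tp, fp, tn, fn = counts
        rep = classification_metrics(ConfusionCounts(tp, fp, tn, fn), mode)
        if tp + fn > 0:
            assert rep.fnr + rep.sensitivity == pytest.approx(1.0, abs=1e-12)
        if tp + fp > 0:
            assert rep.fdr + rep.precision == pytest.approx(1.0, abs=1e-12)
        if mode == "standard" and fp + tn > 0:
            assert rep.fpr == pytest.approx(1.0 - rep.specificity, abs=1e-12)

    @given(counts_st)
    def test_mcc_swap_invariance_and_range(self, counts):
        tp, fp, tn, fn = counts
        a = classification_metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
        b = classification_metrics(ConfusionCounts(tn, fn, tp, fp)).mcc
        if not math.isnan(a):
            assert a == pytest.approx(b, abs=1e-12)
            assert -1.0 - 1e-12 <= a <= 1.0 + 1e-12

    @given(counts_st)
    def test_extra_true_positive_never_hurts(self, counts):
        tp, fp, tn, fn = counts
        before = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
        after = classification_metrics(ConfusionCounts(tp + 1, fp, tn, fn))
        for key in ("accuracy", "sensitivity", "precision"):
            b, a = getattr(before, key), getattr(after, key)
            if not math.isnan(b):
                assert a >= b - 1e-12

    def test_degenerate_counts_flagged_not_raised(self):
        rep = classification_metrics(ConfusionCounts(0, 0, 5, 0))
        assert isinstance(rep.precision, metrics.Undefined)
        assert rep.accuracy == 1.0

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(1, 1, 1, 1), mode="weird")


class TestMaskOverlap:
    def test_identity_and_disjoint(self):
        a = np.zeros((8, 8), int)
        a[2:4, 2:4] = 1
        b = np.zeros((8, 8), int)
        b[5:7, 5:7] = 1
        assert dice(a, a) == 1.0 and jaccard(a, a) == 1.0
        assert dice(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_partial_overlap_counts(self):
        a = np.zeros((4, 4), int)
        a[0, :4] = 1          # |a| = 4
        b = np.zeros((4, 4), int)
        b[0, :2] = 1          # |b| = 2, overlap = 2
        assert dice(a, b) == pytest.approx(2 * 2 / 6)
        assert jaccard(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((5, 5), int)
        assert dice(z, z) == 1.0 and jaccard(z, z) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_dice_jaccard_duality(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng)
        d, j = dice(a, b), jaccard(a, b)
        assert j == pytest.approx(d / (2 - d), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), int), np.zeros((4, 4), int))
        with pytest.raises(ValueError):
            jaccard(np.full((3, 3), 2), np.zeros((3, 3), int))


class TestSerialization:
    def test_csv_columns_and_undefined_cells(self, tmp_path):
        import pandas as pd

        reps = [
            classification_metrics(ConfusionCounts(5, 1, 3, 1)),
            classification_metrics(ConfusionCounts(0, 0, 5, 0)),
        ]
        path = tmp_path / "m.csv"
        metrics.reports_to_csv(reps, path)
        df = pd.read_csv(path)
        assert list(df.columns) == [*metrics.METRIC_COLUMNS, "mode"]
        assert df.loc[1, "precision"] == "undefined"

    def test_json_round(self):
        import json

        rep = classification_metrics(ConfusionCounts(0, 0, 5, 0))
        d = json.loads(metrics.report_to_json(rep))
        assert d["accuracy"] == 1.0 and d["precision"] == "undefined"
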