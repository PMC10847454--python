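"""Evaluation statistics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemogate.errors import (
    DegenerateTestError,
    SeparationError,
    StratificationError,
    UndefinedMetricError,
)
from hemogate.metrics import (
    ConfusionCounts,
    classification_metrics,
    delong_compare,
    fit_marker_model,
    overlap_metrics,
    reclassification_metrics,
    risk_assessment_curves,
    roc_auc,
    stratified_split,
    youden_cutoff,
)


# ------------------------------------------------------------------ overlap

class TestOverlap:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        dice, vs = overlap_metrics(m, m)
        assert dice == 1.0 and vs == 1.0

    def test_disjoint_equal_volumes(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:3], b[3:6] = True, True
        dice, vs = overlap_metrics(a, b)
        assert dice == 0.0
        assert vs == 1.0          # volume similarity ignores overlap

    def test_worked_example(self):
        # |A|=100, |B|=150, |A∩B|=75 -> Dice 0.6, VS 0.8
        a = np.zeros(300, bool)
        b = np.zeros(300, bool)
        a[:100] = True
        b[25:175] = True
        dice, vs = overlap_metrics(a, b)
        assert dice == pytest.approx(2 * 75 / 250)
        assert vs == pytest.approx(1 - 50 / 250)

    def test_both_empty_raises(self):
        with pytest.raises(UndefinedMetricError):
            overlap_metrics(np.zeros(5, bool), np.zeros(5, bool))

    def test_random_masks_match_set_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.random(30) < 0.4
            b = rng.random(30) < 0.4
            if not (a.any() or b.any()):
                continue
            sa = {i for i in range(30) if a[i]}
            sb = {i for i in range(30) if b[i]}
            dice, vs = overlap_metrics(a, b)
            assert dice == pytest.approx(2 * len(sa & sb) / (len(sa) + len(sb)))
            assert vs == pytest.approx(
                1 - abs(len(sa) - len(sb)) / (len(sa) + len(sb)))


# ------------------------------------------------------------------ confusion

def _oracle_confusion(tp, tn, fp, fn):
    """Direct substitution into the defining formulas."""
    import math
    out = {}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else math.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else math.nan
    out["precision"] = tp / (tp + fp) if tp + fp else math.nan
    out["accuracy"] = (tp + tn) / (tp + tn + fp + fn)
    p, r = out["precision"], out["sensitivity"]
    out["f1"] = (2 * p * r / (p + r)
                 if p == p and r == r and (p + r) > 0 else math.nan)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / den if den else math.nan
    return out


class TestClassificationMetrics:
    def test_worked_example(self):
        m = classification_metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["mcc"] == pytest.approx(0.4082, abs=1e-4)

    def test_perfect_and_total_disagreement(self):
        assert classification_metrics(ConfusionCounts(5, 5, 0, 0))["mcc"] == 1.0
        assert classification_metrics(ConfusionCounts(0, 0, 5, 5))["mcc"] == -1.0

    def test_undefined_is_nan_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["precision"])
        assert m["specificity"] == 1.0

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 20, 4)
            if tp + tn + fp + fn == 0:
                continue
            got = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
            want = _oracle_confusion(int(tp), int(tn), int(fp), int(fn))
            for k in want:
                if want[k] != want[k]:           # NaN
                    assert got[k] != got[k], k
                else:
                    assert got[k] == pytest.approx(want[k]), k

    def test_sklearn_cross_check(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        m = classification_metrics(ConfusionCounts.from_predictions(y, p))
        assert m["mcc"] == pytest.approx(matthews_corrcoef(y, p))
        assert m["f1"] == pytest.approx(f1_score(y, p))


# ------------------------------------------------------------------ ROC / AUC

def _auc_pair_oracle(y, s):
    """Enumerate all positive/negative pairs; ties count one half."""
    pos = [v for v, t in zip(s, y) if t]
    neg = [v for v, t in zip(s, y) if not t]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_worked_example(self):
        # pairs: (0.9,0.6)+, (0.9,0.1)+, (0.4,0.6)-, (0.4,0.1)+ -> 3/4
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.2, 0.3])

    def test_random_match_pair_oracle_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = rng.integers(4, 15)
            y = rng.integers(0, 2, n)
            if y.all() or not y.any():
                continue
            s = rng.integers(0, 5, n) / 4.0      # coarse grid forces ties
            assert roc_auc(y, s) == pytest.approx(_auc_pair_oracle(y, s))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=4, max_size=30))
    def test_monotone_transform_invariance(self, data):
        y = [t for t, _ in data]
        if all(y) or not any(y):
            return
        # quantize so affine transforms cannot merge near-equal scores in float64
        s = np.round(np.array([v for _, v in data]), 3)
        base = roc_auc(y, s)
        assert roc_auc(y, 3.0 * s + 2.0) == pytest.approx(base)
        assert roc_auc(y, np.exp(s)) == pytest.approx(base)

    def test_youden_cutoff_recovers_separator(self):
        y = [0, 0, 0, 1, 1, 1]
        s = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        cut = youden_cutoff(y, s)
        assert 0.3 < cut <= 0.7


# ------------------------------------------------------------------ DeLong

class TestDeLong:
    def test_identical_scores(self):
        y = [1, 0, 1, 0, 1, 0]
        s = [0.8, 0.3, 0.6, 0.2, 0.9, 0.4]
        res = delong_compare(y, s, s)
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_aucs_match_roc_auc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = rng.random(40)
        b = rng.random(40)
        res = delong_compare(y, a, b)
        assert res["auc_a"] == pytest.approx(roc_auc(y, a))
        assert res["auc_b"] == pytest.approx(roc_auc(y, b))

    def test_zero_variance_unequal_aucs_raises(self):
        # one positive & one negative: no variance in placements
        with pytest.raises((DegenerateTestError, ValueError)):
            delong_compare([1, 0], [0.9, 0.1], [0.1, 0.9])

    def test_better_model_gets_positive_z(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        good = y + rng.normal(0, 0.4, 60)
        bad = rng.normal(0, 1, 60)
        res = delong_compare(y, good, bad)
        assert res["z"] > 0
        assert res["p"] < 0.05

    def test_variance_close_to_paired_bootstrap(self):
        rng = np.random.default_rng(11)
        n = 100
        y = (rng.random(n) < 0.4).astype(int)
        y[:2] = [0, 1]
        latent = y + rng.normal(0, 1.0, n)
        a = latent + rng.normal(0, 0.5, n)
        b = 0.7 * latent + rng.normal(0, 0.7, n)
        res = delong_compare(y, a, b)
        boots = []
        for _ in range(500):
            idx = rng.integers(0, n, n)
            if y[idx].all() or not y[idx].any():
                continue
            boots.append(roc_auc(y[idx], a[idx]) - roc_auc(y[idx], b[idx]))
        assert res["var_diff"] == pytest.approx(np.var(boots), rel=0.3)


# ------------------------------------------------------------------ NRI / IDI

class TestReclassification:
    def test_identity_gives_zero(self):
        y = [1, 0, 1, 0]
        p = [0.7, 0.2, 0.8, 0.4]
        rs = reclassification_metrics(y, p, p)
        assert rs.nri == 0.0 and rs.idi == 0.0

    def test_worked_example(self):
        # events: 0.2->0.3 (up), 0.4->0.3 (down); nonevent: 0.5->0.4 (down)
        y = [1, 1, 0]
        rs = reclassification_metrics(y, [0.2, 0.4, 0.5], [0.3, 0.3, 0.4])
        assert rs.nri_event == pytest.approx(0.0)
        assert rs.nri_nonevent == pytest.approx(1.0)
        assert rs.nri == pytest.approx(1.0)
        assert rs.idi_event == pytest.approx(0.0)
        assert rs.idi_nonevent == pytest.approx(0.1)
        assert rs.idi == pytest.approx(0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(0.01, 0.99),
                              st.floats(0.01, 0.99)),
                    min_size=4, max_size=25))
    def test_antisymmetry(self, rows):
        y = [t for t, _, _ in rows]
        if all(y) or not any(y):
            return
        pr = [a for _, a, _ in rows]
        pn = [b for _, _, b in rows]
        fwd = reclassification_metrics(y, pr, pn)
        rev = reclassification_metrics(y, pn, pr)
        assert fwd.nri == pytest.approx(-rev.nri)
        assert fwd.idi == pytest.approx(-rev.idi)

    def test_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, n)
            if y.all() or not y.any():
                continue
            rs = reclassification_metrics(y, rng.random(n), rng.random(n))
            assert -1 <= rs.nri_event <= 1
            assert -1 <= rs.nri_nonevent <= 1
            assert -2 <= rs.nri <= 2

    def test_categorical_variant(self):
        y = [1, 0]
        rs = reclassification_metrics(y, [0.1, 0.1], [0.4, 0.12],
                                      cutoffs=(0.3,))
        assert rs.nri_event == 1.0        # crossed the 0.3 boundary
        assert rs.nri_nonevent == 0.0     # moved but stayed in category


# ------------------------------------------------------------------ risk curves

class TestRiskCurves:
    def test_threshold_zero_sensitivity_one(self):
        y = [1, 0, 1, 0, 1]
        p = [0.2, 0.9, 0.7, 0.1, 0.5]
        c = risk_assessment_curves(y, p)
        assert c["event_curve"][0] == 1.0
        assert c["nonevent_curve"][0] == 1.0

    def test_curves_monotone_nonincreasing(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        c = risk_assessment_curves(y, rng.random(40))
        assert np.all(np.diff(c["event_curve"]) <= 1e-12)
        assert np.all(np.diff(c["nonevent_curve"]) <= 1e-12)

    def test_area_between_curves_is_discrimination_slope(self):
        # ∫(sens - (1-spec)) dt = mean p|event - mean p|nonevent, so the
        # between-model difference of this area equals the IDI
        rng = np.random.default_rng(21)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.random(50)
        c = risk_assessment_curves(y, p, n_thresholds=2001)
        area = np.trapezoid(c["event_curve"] - c["nonevent_curve"],
                            c["thresholds"])
        slope = p[y == 1].mean() - p[y == 0].mean()
        assert area == pytest.approx(slope, abs=2e-3)

        p2 = rng.random(50)
        c2 = risk_assessment_curves(y, p2, n_thresholds=2001)
        area2 = np.trapezoid(c2["event_curve"] - c2["nonevent_curve"],
                             c2["thresholds"])
        idi = reclassification_metrics(y, p, p2).idi
        assert area2 - area == pytest.approx(idi, abs=4e-3)


# ------------------------------------------------------------------ marker model

class TestMarkerModel:
    def test_all_zero_columns_intercept_only(self):
        y = np.r_[np.ones(6), np.zeros(14)]
        m = fit_marker_model(np.zeros((20, 8)), y)
        p = m.predict_proba(np.zeros((5, 8)))
        assert p == pytest.approx(np.full(5, 0.3))

    def test_parameter_recovery(self):
        rng = np.random.default_rng(13)
        n = 2000
        x = (rng.random((n, 8)) < 0.4).astype(float)
        beta = np.array([0.8, -0.5, 0.3, 0.0, 0.6, -0.2, 0.1, 0.4])
        eta = -1.0 + x @ beta
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        m = fit_marker_model(x, y)
        se = 2.5 / np.sqrt(n)                   # conservative logistic SE scale
        assert np.all(np.abs(m.coef[1:] - beta) < 6 * se)
        assert abs(m.coef[0] + 1.0) < 0.2

    def test_complete_separation_raises(self):
        x = np.zeros((20, 8))
        y = np.r_[np.ones(10), np.zeros(10)]
        x[:, 2] = y                             # marker 2 separates perfectly
        with pytest.raises(SeparationError):
            fit_marker_model(x, y)

    def test_probabilities_in_open_interval(self):
        rng = np.random.default_rng(17)
        x = (rng.random((200, 8)) < 0.5).astype(float)
        y = rng.integers(0, 2, 200)
        m = fit_marker_model(x, y)
        p = m.predict_proba(x)
        assert np.all((p > 0) & (p < 1))


# ------------------------------------------------------------------ splitting

class TestStratifiedSplit:
    def test_fold_positive_counts_from_cohort_arithmetic(self):
        # 634 patients, 104 positive, 5 folds -> each fold 20 or 21 positives
        y = np.r_[np.ones(104), np.zeros(530)].astype(int)
        test_idx, folds = stratified_split(y, test_frac=0.0, k_folds=5, seed=0)
        assert test_idx.size == 0
        counts = sorted(int(y[f].sum()) for f in folds)
        assert counts in ([20, 21, 21, 21, 21], [21, 21, 21, 21, 20])
        assert set(np.concatenate(folds).tolist()) == set(range(634))

    def test_folds_disjoint_and_cover_training(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        test_idx, folds = stratified_split(y, test_frac=0.2, k_folds=5, seed=3)
        allf = np.concatenate(folds)
        assert len(set(allf.tolist())) == allf.size
        assert set(allf.tolist()) | set(test_idx.tolist()) == set(range(100))
        assert not set(allf.tolist()) & set(test_idx.tolist())

    def test_deterministic_by_seed(self):
        y = np.r_[np.ones(25), np.zeros(75)].astype(int)
        a = stratified_split(y, 0.2, 5, seed=9)
        b = stratified_split(y, 0.2, 5, seed=9)
        assert np.array_equal(a[0], b[0])
        for fa, fb in zip(a[1], b[1]):
            assert np.array_equal(fa, fb)

    def test_class_too_small_raises(self):
        y = np.r_[np.ones(3), np.zeros(50)].astype(int)
        with pytest.raises(StratificationError):
            stratified_split(y, 0.2, 5, seed=0)
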