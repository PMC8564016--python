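import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ffram.diagnostics import (aggregate_per_patient, auc_variance,
                               bland_altman, confusion_metrics, delong_test,
                               diagnostic_report, pearson_r, roc_auc)


def brute_force_auc(scores, truth, lower_is_positive):
    s = -np.asarray(scores, float) if lower_is_positive else np.asarray(scores, float)
    pos = s[np.asarray(truth, bool)]
    neg = s[~np.asarray(truth, bool)]
    wins = sum(1.0 if x > y else (0.5 if x == y else 0.0)
               for x, y in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_hand_worked_2x2(self):
        truth = [True] * 12 + [False] * 8
        calls = [True] * 9 + [False] * 3 + [True] * 1 + [False] * 7
        m = confusion_metrics(calls, truth)
        assert math.isclose(m.sensitivity, 0.75)
        assert math.isclose(m.specificity, 0.875)
        assert math.isclose(m.accuracy, 0.80)
        assert math.isclose(m.ppv, 0.90)
        assert math.isclose(m.npv, 0.70)
        assert math.isclose(m.lr_pos, 6.0)

    def test_perfect_calls(self):
        truth = [True, True, False, False]
        m = confusion_metrics(truth, truth)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0
        assert m.lr_neg == 0.0
        assert m.lr_pos == float("inf")

    def test_inverted_calls_swap_rates(self):
        rng = np.random.default_rng(0)
        truth = rng.random(40) < 0.5
        truth[:2] = [True, False]
        calls = rng.random(40) < 0.5
        a = confusion_metrics(calls, truth)
        b = confusion_metrics(~calls, truth)
        assert math.isclose(b.sensitivity, 1 - a.sensitivity)
        assert math.isclose(b.specificity, 1 - a.specificity)

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            confusion_metrics([True, False], [True, True])

    def test_accuracy_identity(self):
        rng = np.random.default_rng(1)
        truth = rng.random(50) < 0.4
        truth[:2] = [True, False]
        calls = rng.random(50) < 0.5
        m = confusion_metrics(calls, truth)
        n = m.n_pos + m.n_neg
        assert math.isclose(
            m.accuracy,
            (m.sensitivity * m.n_pos + m.specificity * m.n_neg) / n)


class TestRocAuc:
    def test_four_case_hand_value(self):
        scores = [0.8, 0.4, 0.6, 0.2]
        truth = [True, True, False, False]
        assert roc_auc(scores, truth, lower_is_positive=False) == 0.75

    def test_separated_and_ties(self):
        assert roc_auc([1, 2, 3, 4], [False, False, True, True], False) == 1.0
        assert roc_auc([1, 1, 1, 1], [True, False, True, False], False) == 0.5

    def test_orientation_flip(self):
        scores = [0.9, 0.7, 0.85, 0.6]
        truth = [False, True, False, True]
        a = roc_auc(scores, truth, lower_is_positive=True)
        b = roc_auc(scores, truth, lower_is_positive=False)
        assert math.isclose(a + b, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        truth = rng.random(n) < 0.5
        truth[:2] = [True, False]
        scores = np.round(rng.random(n), 1)  # rounding forces ties
        lower = bool(rng.random() < 0.5)
        assert math.isclose(roc_auc(scores, truth, lower),
                            brute_force_auc(scores, truth, lower),
                            rel_tol=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        truth = rng.random(200) < 0.4
        truth[:2] = [True, False]
        scores = rng.normal(size=200) + truth
        assert math.isclose(roc_auc(scores, truth, False),
                            roc_auc_score(truth, scores), rel_tol=1e-12)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(0)
        truth = np.array([True] * 10 + [False] * 10)
        s = rng.normal(size=20) + truth
        res = delong_test(s, s, truth, False, False)
        assert res.auc_a == res.auc_b
        assert res.p == 1.0

    def test_variance_positive_nondegenerate(self):
        rng = np.random.default_rng(1)
        truth = np.array([True] * 12 + [False] * 15)
        a = rng.normal(size=27) + truth
        b = rng.normal(size=27) + truth
        res = delong_test(a, b, truth, False, False)
        assert res.var_a > 0 and res.var_b > 0

    def test_mixed_orientation_comparison(self):
        # an FFR-like and a stenosis-like index carrying the same signal
        rng = np.random.default_rng(2)
        truth = np.array([True] * 20 + [False] * 20)
        latent = rng.normal(size=40) + truth
        ffr_like = 1.0 - 0.1 * latent
        ds_like = 0.3 + 0.1 * latent
        res = delong_test(ffr_like, ds_like, truth, True, False)
        assert math.isclose(res.auc_a, res.auc_b, rel_tol=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], [True, False], False, False)

    def test_null_calibration(self):
        # type-I error of the paired test at alpha=0.05 under a shared
        # latent + independent noise null
        rng = np.random.default_rng(2026)
        truth = np.array([True] * 15 + [False] * 15)
        ps = []
        for _ in range(500):
            latent = np.where(truth, rng.normal(1.0, 1.0, 30),
                              rng.normal(0.0, 1.0, 30))
            a = latent + rng.normal(0, 1, 30)
            b = latent + rng.normal(0, 1, 30)
            ps.append(delong_test(a, b, truth, False, False).p)
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= rate <= 0.08


class TestAgreement:
    def test_hand_values(self):
        ba = bland_altman([0.8, 0.6], [0.7, 0.7])
        assert math.isclose(ba.bias, 0.0, abs_tol=1e-15)
        assert math.isclose(ba.sd, 0.1414, abs_tol=5e-4)

    def test_identical_vectors(self):
        ba = bland_altman([1, 2, 3], [1, 2, 3])
        assert ba.bias == 0.0 and ba.sd == 0.0

    def test_shift_property_and_reorder_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = bland_altman(x, y)
        shifted = bland_altman(x, y + 0.5)
        assert math.isclose(shifted.bias, base.bias + 0.5, rel_tol=1e-12)
        assert math.isclose(shifted.sd, base.sd, rel_tol=1e-12)
        perm = rng.permutation(30)
        re = bland_altman(x[perm], y[perm])
        assert math.isclose(re.bias, base.bias, rel_tol=1e-12)
        assert math.isclose(re.sd, base.sd, rel_tol=1e-12)

    def test_pearson_exact_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert math.isclose(pearson_r(x, 2 * x + 1).r, 1.0)
        assert math.isclose(pearson_r(x, -x).r, -1.0)

    def test_pearson_independent_near_zero(self):
        rng = np.random.default_rng(4)
        r = pearson_r(rng.normal(size=10000), rng.normal(size=10000)).r
        assert abs(r) < 0.05

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPerPatient:
    def frame(self):
        return pd.DataFrame({
            "vessel_id": ["v1", "v2", "v3"],
            "patient_id": ["p1", "p2", "p2"],
            "ffr_invasive": [0.9, 0.9, 0.7],
            "ffr_am": [0.85, 0.88, 0.75],
            "ds_ctca": [0.3, 0.4, 0.6],
        })

    def test_single_vessel_patients_unchanged(self):
        df = self.frame().iloc[:1]
        out = aggregate_per_patient(df, {"ffr_am": True, "ds_ctca": False})
        assert len(out) == 1
        assert out.loc[0, "ffr_am"] == 0.85

    def test_worst_vessel_rule(self):
        out = aggregate_per_patient(self.frame(),
                                    {"ffr_am": True, "ds_ctca": False})
        p2 = out[out.patient_id == "p2"].iloc[0]
        assert p2.ffr_invasive == 0.7 and p2.ffr_am == 0.75
        assert p2.ds_ctca == 0.6
        assert bool(p2.ischemic)

    def test_patient_count(self):
        out = aggregate_per_patient(self.frame(), {"ffr_am": True})
        assert len(out) == 2

    def test_report_shapes_and_auc_one_for_own_truth(self):
        rng = np.random.default_rng(6)
        n = 60
        ffr = rng.uniform(0.5, 1.0, n)
        df = pd.DataFrame({
            "vessel_id": [f"v{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "ffr_invasive": ffr,
            "ffr_am": ffr,  # scored by its own truth
        })
        rep = diagnostic_report(df, {"ffr_am": (True, 0.80)})
        row = rep.iloc[0]
        assert row.auc == 1.0 and row.accuracy == 1.0
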