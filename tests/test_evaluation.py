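"""Macro metrics, CV partitioning, significance tests, neighbor consistency."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import precision_score, recall_score

from gcanddi.evaluation import (
    ConfusionCounts,
    compare_methods,
    confusion_counts,
    fivefold_cv,
    format_percent,
    macro_metrics,
    neighbor_consistency,
)


def brute_force_macro(y_true, y_pred):
    """Independent recount of the macro metrics from first principles."""
    n_types = y_true.shape[1]
    recalls, precisions = [], []
    for t in range(n_types):
        tp = int(((y_true[:, t] == 1) & (y_pred[:, t] == 1)).sum())
        fp = int(((y_true[:, t] == 0) & (y_pred[:, t] == 1)).sum())
        fn = int(((y_true[:, t] == 1) & (y_pred[:, t] == 0)).sum())
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
    r = sum(recalls) / n_types
    p = sum(precisions) / n_types
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return r, p, f1


class TestMacroMetrics:
    def test_perfect_predictions_score_one(self):
        counts = ConfusionCounts(tp=[3, 2], fp=[0, 0], fn=[0, 0], tn=[2, 3])
        m = macro_metrics(counts)
        assert m.macro_recall == m.macro_precision == m.macro_f1 == 1.0

    def test_hand_arithmetic_two_type_example(self):
        counts = ConfusionCounts(tp=[3, 1], fp=[1, 3], fn=[1, 3], tn=[0, 0])
        m = macro_metrics(counts)
        assert m.macro_recall == pytest.approx(0.5)
        assert m.macro_precision == pytest.approx(0.5)
        assert m.macro_f1 == pytest.approx(0.5)

    def test_empty_type_contributes_zero(self):
        counts = ConfusionCounts(tp=[5, 0], fp=[0, 0], fn=[0, 0], tn=[0, 5])
        m = macro_metrics(counts)
        assert m.macro_recall == pytest.approx(0.5)
        assert m.macro_precision == pytest.approx(0.5)

    def test_zero_types_is_a_contract_error(self):
        with pytest.raises(ValueError):
            macro_metrics(ConfusionCounts(tp=[], fp=[], fn=[], tn=[]))

    def test_f1_is_harmonic_mean_of_the_macro_averages(self, rng):
        for _ in range(20):
            t = rng.integers(0, 2, size=(30, 5))
            p = rng.integers(0, 2, size=(30, 5))
            m = macro_metrics(confusion_counts(t, p))
            if m.macro_precision + m.macro_recall > 0:
                expect = (2 * m.macro_precision * m.macro_recall
                          / (m.macro_precision + m.macro_recall))
                assert m.macro_f1 == pytest.approx(expect, abs=1e-12)

    def test_matches_sklearn_macro_recall_precision(self, rng):
        t = rng.integers(0, 2, size=(50, 6))
        p = rng.integers(0, 2, size=(50, 6))
        m = macro_metrics(confusion_counts(t, p))
        assert m.macro_recall == pytest.approx(
            recall_score(t, p, average="macro", zero_division=0))
        assert m.macro_precision == pytest.approx(
            precision_score(t, p, average="macro", zero_division=0))


class _ConstantClassifier:
    """Always predicts one fixed type; sklearn-compatible for CV."""

    def __init__(self, label="t0"):
        self.label = label

    def get_params(self, deep=True):
        return {"label": self.label}

    def set_params(self, **kw):
        self.__dict__.update(kw)
        return self

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.array([self.label] * len(X))


class TestFivefoldCv:
    def _balanced(self, n_per=20):
        X = np.arange(4 * n_per * 2, dtype=float).reshape(4 * n_per, 2)
        y = np.repeat([f"t{i}" for i in range(4)], n_per)
        return X, y

    def test_partition_sizes_and_disjointness(self):
        from sklearn.model_selection import StratifiedKFold
        X, y = self._balanced(n_per=25)
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, test in splitter.split(X, y):
            assert len(test) == 20
            seen.extend(test)
        assert sorted(seen) == list(range(100))

    def test_constant_classifier_on_balanced_four_types(self):
        X, y = self._balanced()
        folds, summary = fivefold_cv(_ConstantClassifier("t0"), X, y, seed=1)
        assert len(folds) == 5
        for m in folds:
            # recall: 1 for t0, 0 elsewhere; closed form 0.25
            assert m.macro_recall == pytest.approx(0.25)
        assert summary["macro_recall"]["mean"] == pytest.approx(0.25)

    def test_identical_seed_reproduces_folds(self):
        X, y = self._balanced()
        a = fivefold_cv(_ConstantClassifier(), X, y, seed=3)[0]
        b = fivefold_cv(_ConstantClassifier(), X, y, seed=3)[0]
        for ma, mb in zip(a, b):
            assert ma.macro_f1 == mb.macro_f1

    def test_percent_formatting(self):
        assert format_percent(np.array([0.951, 0.933, 0.972, 0.94, 0.969])) == \
            "95.3% ± 1.7%"


class TestCompareMethods:
    def test_identical_fold_vectors_give_p_one(self):
        a = np.array([0.9, 0.91, 0.92, 0.9, 0.93])
        assert compare_methods(a, a.copy()) == 1.0

    def test_well_separated_vectors_give_small_p(self):
        a = np.array([0.95, 0.96, 0.955, 0.962, 0.958])
        b = np.array([0.60, 0.61, 0.605, 0.612, 0.608])
        assert compare_methods(a, b) < 0.01

    def test_matches_scipy_paired_ttest(self):
        a = np.array([0.5, 0.5, 0.5, 0.5, 0.6])
        b = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        assert compare_methods(a, b) == pytest.approx(stats.ttest_rel(a, b).pvalue)

    def test_fewer_than_two_folds_is_an_error(self):
        with pytest.raises(ValueError):
            compare_methods(np.array([0.5]), np.array([0.6]))


class TestNeighborConsistency:
    def test_identity_case_yields_fraction_one(self, rng):
        # concordant group forms a tight cluster; predicted set == that group
        concordant = [f"c{i}" for i in range(5)]
        other = [f"o{i}" for i in range(5)]
        ids = concordant + other
        feats = np.vstack([rng.normal(0, 0.01, size=(5, 3)),
                           rng.normal(10, 0.01, size=(5, 3))])
        frac = neighbor_consistency(concordant,
                                    {"inc": concordant, "dec": other},
                                    "inc", feats, ids)
        assert frac == 1.0

    def test_random_features_give_group_share(self, rng):
        ids = [f"d{i}" for i in range(40)]
        groups = {"inc": ids[:20], "dec": ids[20:]}
        fracs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            feats = r.standard_normal((40, 4))
            preds = [f"p{i}" for i in range(10)]
            all_ids = ids + preds
            all_feats = np.vstack([feats, r.standard_normal((10, 4))])
            fracs.append(neighbor_consistency(preds, groups, "inc",
                                              all_feats, all_ids))
        # expectation is the group-size share (0.5) within binomial error
        assert abs(np.mean(fracs) - 0.5) < 0.1

    def test_ties_break_by_drug_id_order_matching_exhaustive_scan(self):
        ids = ["a", "b", "c", "p"]
        feats = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 5.0], [1.0, 0.0]])
        # 'a' and 'b' tie for nearest to 'p'; id order picks 'a' (group g1)
        frac = neighbor_consistency(["p"], {"g1": ["a"], "g2": ["b", "c"]},
                                    "g1", feats, ids)
        assert frac == 1.0

    def test_empty_groups_are_an_error(self, rng):
        with pytest.raises(ValueError):
            neighbor_consistency(["p"], {"g1": [], "g2": ["a"]}, "g1",
                                 np.ones((3, 2)), ["a", "p", "q"])
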