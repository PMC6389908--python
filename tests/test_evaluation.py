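import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exhaustive_cutoff, pairwise_auc
from mirisk import evaluation as ev
from mirisk import spca_model as spca


class TestROCAndAUC:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert ev.roc_and_auc(scores, labels).auc == 1.0

    def test_all_tied_scores_give_auc_half(self):
        curve = ev.roc_and_auc(np.ones(10), np.repeat([0, 1], 5))
        assert curve.auc == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0, 1, 12), 1)  # rounding forces ties
        labels = np.repeat([1, 0], 6)
        curve = ev.roc_and_auc(scores, labels)
        assert curve.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_trapezoid_area_equals_mann_whitney(self, rng):
        scores = np.round(rng.normal(0, 1, 60), 1)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        curve = ev.roc_and_auc(scores, labels)
        # integrate in curve (threshold) order: x = 1 - spec runs downward
        area = -np.trapezoid(curve.sensitivity, 1 - curve.specificity)
        assert area == pytest.approx(curve.auc, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        curve = ev.roc_and_auc(scores, labels)
        assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
        assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0
        assert (np.diff(curve.sensitivity) <= 0).all()

    def test_negated_scores_flip_auc(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a1 = ev.roc_and_auc(scores, labels).auc
        a2 = ev.roc_and_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_and_auc(np.arange(5.0), np.ones(5))


class TestOptimalCutoff:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0, 1, 25), 1)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        curve = ev.roc_and_auc(scores, labels)
        assert ev.optimal_cutoff(curve) == exhaustive_cutoff(scores, labels)

    def test_perfectly_separated_deterministic(self):
        scores = np.array([3.0, 4.0, 5.0, 0.0, 1.0, 2.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        curve = ev.roc_and_auc(scores, labels)
        # every threshold in [2, 3) is optimal; the tie rule picks the
        # lowest enumerated one, the largest control score
        assert ev.optimal_cutoff(curve) == 2.0


class TestConfusionMetrics:
    def test_prospective_conversion_table_metrics(self):
        """10 true converters all caught, 4 predicted-negative all correct,
        18 false alarms out of 22 non-converters."""
        metrics = ev.confusion_metrics(ev.ContingencyTable(tp=10, fp=18, fn=0, tn=4))
        assert metrics.sensitivity == 1.0
        assert metrics.npv == 1.0
        assert metrics.specificity == pytest.approx(4 / 22)
        assert round(metrics.specificity, 2) == 0.18

    def test_all_correct_gives_ones(self):
        metrics = ev.confusion_metrics(ev.ContingencyTable(tp=5, fp=0, fn=0, tn=7))
        assert (
            metrics.accuracy == metrics.sensitivity == metrics.specificity
            == metrics.ppv == metrics.npv == 1.0
        )

    def test_random_table_matches_hand_formulas(self, rng):
        tp, fp, fn, tn = rng.integers(1, 50, 4)
        m = ev.confusion_metrics(ev.ContingencyTable(int(tp), int(fp), int(fn), int(tn)))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.ppv == pytest.approx(tp / (tp + fp))
        assert m.npv == pytest.approx(tn / (tn + fn))

    def test_zero_denominator_reported_missing(self):
        metrics = ev.confusion_metrics(ev.ContingencyTable(tp=0, fp=0, fn=0, tn=5))
        assert metrics.sensitivity is None
        assert metrics.ppv is None
        assert metrics.specificity == 1.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ev.confusion_metrics(ev.ContingencyTable(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ev.ContingencyTable(tp=-1, fp=0, fn=0, tn=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_metrics_bounds_and_accuracy_between_sens_spec(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = ev.confusion_metrics(ev.ContingencyTable(tp, fp, fn, tn))
        for value in (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv):
            assert value is None or 0.0 <= value <= 1.0
        if m.sensitivity is not None and m.specificity is not None:
            lo = min(m.sensitivity, m.specificity) - 1e-12
            hi = max(m.sensitivity, m.specificity) + 1e-12
            assert lo <= m.accuracy <= hi


class TestProspectiveValidate:
    def _model(self, cutoff):
        pca = spca.PCAModel(
            mirna_ids=["a"], center=np.zeros(1),
            loadings=np.eye(1), explained_variance=np.ones(1),
        )
        return spca.RiskModel(
            disease="AD", T=1.0, m=1, pca=pca, betas=np.ones(1), pi_cutoff=cutoff
        )

    def test_cutoff_above_all_pis_predicts_nobody(self):
        model = self._model(cutoff=100.0)
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        table, metrics, _ = ev.prospective_validate(model, expr, np.array([1, 1, 0]))
        assert table.tp == 0 and table.fp == 0
        assert metrics.sensitivity == 0.0
        assert metrics.ppv is None

    def test_unset_cutoff_raises(self):
        model = self._model(cutoff=None)
        with pytest.raises(ValueError, match="cutoff"):
            ev.prospective_validate(
                model, pd.DataFrame({"a": [1.0]}), np.array([1])
            )

    def test_missing_model_feature_raises(self):
        model = self._model(cutoff=0.0)
        with pytest.raises(ValueError, match="a"):
            ev.prospective_validate(
                model, pd.DataFrame({"b": [1.0]}), np.array([1])
            )

    def test_counts_cross_tabulated_correctly(self):
        model = self._model(cutoff=0.0)
        expr = pd.DataFrame({"a": [1.0, 1.0, -1.0, -1.0]})
        observed = np.array([1, 0, 1, 0])
        table, _, pi = ev.prospective_validate(model, expr, observed)
        assert (table.tp, table.fp, table.fn, table.tn) == (1, 1, 1, 1)
        assert list(pi) == [1.0, 1.0, -1.0, -1.0]
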