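"""Confusion summaries, the six performance measures, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scrules.dataset import ExpressionDataset
from scrules.metrics import (
    ConfusionCounts,
    compute_metrics,
    confusion,
    cross_validate,
)
from scrules.simulate import NEGATIVE, POSITIVE, PlantedRule, SyntheticSpec, generate


class TestConfusion:
    @pytest.mark.parametrize(
        "y_true, y_pred, expected",
        [
            (list("++--"), list("++--"), (2, 0, 2, 0)),
            (list("++--"), list("--++"), (0, 2, 0, 2)),
            (list("+++--"), list("+-++-"), (2, 1, 1, 1)),
        ],
    )
    def test_hand_tallies(self, y_true, y_pred, expected):
        c = confusion(y_true, y_pred, positive_class="+")
        assert (c.TP, c.FP, c.TN, c.FN) == expected
        assert c.total == len(y_true)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown|ambiguous"):
            confusion(["+", "-"], ["+", "?"], positive_class="+",
                      negative_class="-")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], positive_class="+")


class TestComputeMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = compute_metrics(ConfusionCounts(10, 0, 10, 0))
        assert m.as_dict() == pytest.approx(
            {"SN": 1, "SP": 1, "ACC": 1, "MCC": 1, "precision": 1, "F1": 1}
        )

    def test_symmetric_half_right(self):
        m = compute_metrics(ConfusionCounts(5, 5, 5, 5))
        assert (m.SN, m.SP, m.ACC, m.precision, m.F1) == (0.5,) * 5
        assert m.MCC == 0.0

    def test_hand_evaluated_mixed_case(self):
        m = compute_metrics(ConfusionCounts(8, 2, 6, 4))
        assert m.SN == pytest.approx(0.6667, abs=1e-4)
        assert m.SP == 0.75
        assert m.ACC == pytest.approx(0.70)
        assert m.precision == pytest.approx(0.80)
        assert m.F1 == pytest.approx(0.7273, abs=1e-4)
        assert m.MCC == pytest.approx(0.4082, abs=1e-4)

    @pytest.mark.parametrize(
        "counts, zeros",
        [
            (ConfusionCounts(0, 0, 5, 5), ("SN", "precision", "MCC", "F1")),
            (ConfusionCounts(5, 5, 0, 0), ("SP", "MCC")),
            (ConfusionCounts(0, 5, 5, 0), ("SN", "precision", "F1")),
        ],
    )
    def test_zero_denominator_conventions(self, counts, zeros):
        m = compute_metrics(counts).as_dict()
        for key in zeros:
            assert m[key] == 0.0

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        tn=st.integers(0, 40), fn=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_swapping_the_positive_class_swaps_sn_and_sp(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        swapped = compute_metrics(ConfusionCounts(tn, fn, tp, fp))
        assert swapped.SN == pytest.approx(m.SP)
        assert swapped.SP == pytest.approx(m.SN)
        assert swapped.ACC == pytest.approx(m.ACC)
        assert swapped.MCC == pytest.approx(m.MCC)
        assert m.F1 <= 1 and -1 <= m.MCC <= 1

    def test_f1_is_harmonic_mean_of_sn_and_precision(self):
        m = compute_metrics(ConfusionCounts(7, 3, 11, 2))
        assert m.F1 == pytest.approx(
            2 * m.SN * m.precision / (m.SN + m.precision)
        )


def _stump_fit_predict(X_train, y_train, X_test):
    from sklearn.tree import DecisionTreeClassifier

    model = DecisionTreeClassifier(max_depth=2, random_state=0)
    model.fit(X_train, y_train.astype(str))
    return model.predict(X_test)


class TestCrossValidate:
    def test_perfectly_separable_data_scores_f1_one(self):
        spec = SyntheticSpec(n_pos=60, n_neg=40, n_genes=5, seed=2,
                             planted_rule_genes=[PlantedRule(0, 3.0, ">=", POSITIVE)])
        ds, _ = generate(spec)
        for k in (2, 5, 10):
            cv = cross_validate(ds, ds.gene_ids, _stump_fit_predict, k=k, seed=1)
            assert cv.pooled.F1 == 1.0

    def test_fold_bookkeeping(self):
        ds, _ = generate(SyntheticSpec(n_pos=60, n_neg=60, n_genes=5, seed=3))
        cv = cross_validate(ds, ds.gene_ids, _stump_fit_predict,
                            k=10, repeats=3, seed=0)
        assert len(cv.fold_counts) == 30
        assert len(cv.per_repeat) == 3
        assert cv.pooled_counts.total == 3 * ds.n_cells

    def test_pooled_metrics_invariant_to_fold_order(self):
        ds, _ = generate(SyntheticSpec(n_pos=50, n_neg=50, n_genes=5, seed=4))
        cv = cross_validate(ds, ds.gene_ids, _stump_fit_predict, k=5, seed=0)
        shuffled = list(reversed(cv.fold_counts))
        pooled = shuffled[0]
        for c in shuffled[1:]:
            pooled = pooled + c
        assert pooled == cv.pooled_counts

    def test_null_accuracy_near_chance_across_seeds(self):
        """Permuted labels: balanced 200-cell data, 10-fold CV accuracy
        stays within 3 Monte-Carlo SDs of 0.5 over 20 seeds."""
        from scrules.simulate import permute_labels

        ds, _ = generate(SyntheticSpec(n_pos=100, n_neg=100, n_genes=10, seed=5))
        accs = []
        for seed in range(20):
            null = permute_labels(ds, seed=seed)
            cv = cross_validate(null, ds.gene_ids, _stump_fit_predict,
                                k=10, seed=seed)
            accs.append(cv.pooled.ACC)
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * max(se, 1e-6) + 0.02

    def test_small_k_with_rare_class_raises_helpfully(self):
        values = np.random.default_rng(0).random((8, 3))
        ds = ExpressionDataset(
            values=values, gene_ids=["a", "b", "c"],
            cell_ids=[f"c{i}" for i in range(8)],
            labels=np.array([POSITIVE] + [NEGATIVE] * 7, dtype=object),
        )
        with pytest.raises(ValueError):
            cross_validate(ds, ds.gene_ids, _stump_fit_predict, k=4, seed=0)

    def test_k_below_two_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="at least 2"):
            cross_validate(tiny_dataset, tiny_dataset.gene_ids,
                           _stump_fit_predict, k=1)
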