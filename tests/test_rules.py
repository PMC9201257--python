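"""FOIL gain, discretization, Johnson reducer, RIPPER, rule application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scrules.dataset import ExpressionDataset
from scrules.rules import (
    Condition,
    Rule,
    RuleSet,
    RipperParams,
    apply_rules,
    evaluate_rules,
    foil_gain,
    johnson_reduce_arrays,
    mdl_discretize,
    ripper,
)
from scrules.rules import _ruleset_dl  # noqa: for the DL monotonicity check
from scrules.simulate import (
    NEGATIVE,
    POSITIVE,
    PlantedRule,
    SyntheticSpec,
    generate,
)


class TestFoilGain:
    def test_hand_derived_values(self):
        assert foil_gain(10, 10, 5, 0) == pytest.approx(5.0)
        assert foil_gain(10, 10, 4, 1) == pytest.approx(2.7123, abs=1e-4)

    def test_zero_positive_coverage_convention(self):
        assert foil_gain(10, 10, 0, 3) == 0.0

    def test_unchanged_precision_gives_zero_gain(self):
        # p1/(p1+n1) == p0/(p0+n0) makes the log terms identical
        assert foil_gain(10, 10, 5, 5) == 0.0
        assert foil_gain(9, 3, 6, 2) == 0.0

    @given(
        p0=st.integers(1, 50), n0=st.integers(0, 50),
        p1=st.integers(0, 50), n1=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_gain_positive_iff_precision_improves(self, p0, n0, p1, n1):
        if p1 > p0 or n1 > n0:
            with pytest.raises(ValueError):
                foil_gain(p0, n0, p1, n1)
            return
        gain = foil_gain(p0, n0, p1, n1)
        if p1 == 0:
            assert gain == 0.0
        else:
            before = p0 / (p0 + n0)
            after = p1 / (p1 + n1)
            assert (gain > 0) == (after > before)


class TestMdlDiscretize:
    def test_clean_two_class_split_yields_one_cut_in_the_gap(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.uniform(0, 3, 50), rng.uniform(5, 8, 50)])
        y = np.repeat([0, 1], 50)
        cuts = mdl_discretize(values, y)
        assert len(cuts) == 1
        assert 3 < cuts[0] < 5

    def test_uninformative_feature_gets_no_cut(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        assert mdl_discretize(values, y) == []


class TestJohnsonReduce:
    def test_single_separating_feature_is_the_reduct(self):
        rng = np.random.default_rng(2)
        X = np.zeros((40, 3))
        y = np.repeat([1, 0], 20)
        X[:, 1] = np.where(y == 1, rng.uniform(5, 8, 40), rng.uniform(0, 3, 40))
        X[:, 0] = 2.0  # constant
        X[:, 2] = 2.0
        assert johnson_reduce_arrays(X, y, ["f1", "f2", "f3"]) == ["f2"]

    def test_greedy_cover_picks_the_feature_discerning_most_pairs(self):
        # Pairs (by differently-labeled sample pairs): f1 discerns {a,b},
        # f2 discerns {b,c}, f3 discerns {a,b,c} -> the reduct is {f3},
        # verified against exhaustive cover enumeration by hand.
        # samples: p1 (pos) vs n1,n2,n3 (neg) -> pairs a,b,c
        X = np.array(
            [
                # f1    f2    f3
                [10.0, 10.0, 10.0],  # p1
                [0.0, 10.0, 0.0],    # n1 (pair a: f1, f3)
                [0.0, 0.0, 0.0],     # n2 (pair b: f1, f2, f3)
                [10.0, 0.0, 0.0],    # n3 (pair c: f2, f3)
            ]
        )
        y = np.array([1, 0, 0, 0])
        assert johnson_reduce_arrays(X, y, ["f1", "f2", "f3"]) == ["f3"]

    def test_reduct_invariant_to_feature_column_order(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1, 0], 30)
        X = rng.uniform(0, 1, size=(60, 4))
        X[:, 2] = np.where(y == 1, rng.uniform(5, 8, 60), rng.uniform(0, 3, 60))
        names = ["f1", "f2", "f3", "f4"]
        reduct = johnson_reduce_arrays(X, y, names)
        perm = [3, 0, 2, 1]
        reduct_perm = johnson_reduce_arrays(
            X[:, perm], y, [names[j] for j in perm]
        )
        assert set(reduct) == set(reduct_perm) == {"f3"}

    def test_indiscernible_classes_are_an_error(self):
        X = np.ones((10, 2))
        y = np.repeat([1, 0], 5)
        with pytest.raises(ValueError, match="indiscernible"):
            johnson_reduce_arrays(X, y, ["f1", "f2"])


def _one_dim_gap_dataset(n: int = 200, seed: int = 0) -> ExpressionDataset:
    """Class A iff gene <= 3.0, class B iff >= 5.0, noiseless."""
    rng = np.random.default_rng(seed)
    n_a = n // 2 - 10
    n_b = n - n_a
    values = np.concatenate(
        [rng.uniform(0.0, 3.0, n_a), rng.uniform(5.0, 9.0, n_b)]
    )[:, None]
    labels = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
    return ExpressionDataset(
        values=values, gene_ids=["g1"],
        cell_ids=[f"c{i}" for i in range(n)], labels=labels,
        positive_class="A",
    )


class TestRipper:
    def test_one_dim_gap_recovers_a_single_threshold_rule(self):
        ds = _one_dim_gap_dataset(seed=1)
        rs = ripper(ds, RipperParams(seed=0))
        assert len(rs.rules) == 1
        rule = rs.rules[0]
        assert len(rule.conditions) == 1
        assert 3.0 < rule.conditions[0].threshold < 5.0
        pred = apply_rules(rs, ds)
        assert np.mean(pred == ds.labels) == 1.0

    def test_minority_class_is_learned_majority_is_default(self):
        ds = _one_dim_gap_dataset(seed=2)  # A is the minority class
        rs = ripper(ds, RipperParams(seed=0))
        assert rs.rules[0].predicted_class == "A"
        assert rs.default_class == "B"

    def test_single_class_input_gives_empty_ruleset(self):
        values = np.random.default_rng(0).random((10, 2))
        ds = ExpressionDataset(
            values=values, gene_ids=["g1", "g2"],
            cell_ids=[f"c{i}" for i in range(10)],
            labels=np.array(["A"] * 10, dtype=object),
        )
        rs = ripper(ds, RipperParams(seed=0))
        assert len(rs.rules) == 0 and rs.default_class == "A"

    def test_every_rule_covers_a_positive(self):
        spec = SyntheticSpec(n_pos=80, n_neg=60, n_genes=6, dropout_rate=0.5,
                             seed=4, rule_gap=0.25,
                             planted_rule_genes=[PlantedRule(0, 4.0, ">=", POSITIVE)])
        ds, _ = generate(spec)
        rs = ripper(ds, RipperParams(seed=0))
        assert all(rule.p >= 1 for rule in rs.rules)

    def test_deterministic_given_seed(self):
        ds = _one_dim_gap_dataset(seed=3)
        a = ripper(ds, RipperParams(seed=7))
        b = ripper(ds, RipperParams(seed=7))
        assert [(r.conditions, r.p, r.n) for r in a.rules] == [
            (r.conditions, r.p, r.n) for r in b.rules
        ]

    def test_conjunction_recovered_with_matching_operators(self):
        ds, _ = generate(SyntheticSpec(n_pos=300, n_neg=200, n_genes=20,
                                       dropout_rate=0.5, seed=5))
        from scrules.simulate import plant_conjunction

        plant_conjunction(
            ds, [(0, ">=", 2.7722), (1, "<=", 15.2306)],
            target_class=NEGATIVE, seed=1,
        )
        rs = ripper(ds, RipperParams(seed=0))
        assert len(rs.rules) >= 1
        rule = rs.rules[0]
        used = {(c.gene_id, c.operator) for c in rule.conditions}
        assert used == {("g1", ">="), ("g2", "<=")}
        pred = apply_rules(rs, ds)
        assert np.mean(pred == ds.labels) == 1.0

    def test_optimization_never_raises_description_length(self):
        spec = SyntheticSpec(n_pos=120, n_neg=90, n_genes=8, dropout_rate=0.5,
                             seed=6, rule_noise=0.1,
                             planted_rule_genes=[PlantedRule(0, 4.0, ">=", POSITIVE)])
        ds, _ = generate(spec)
        gene_index = {g: j for j, g in enumerate(ds.gene_ids)}
        y_pos_class = min(
            set(ds.labels), key=lambda c: (np.sum(ds.labels == c), c)
        )
        y_pos = np.asarray(ds.labels) == y_pos_class
        n_possible = 2 * ds.n_genes
        dls = []
        for rounds in (0, 2):
            rs = ripper(ds, RipperParams(seed=0, optimization_rounds=rounds))
            dls.append(
                _ruleset_dl(rs.rules, ds.values, y_pos, gene_index, n_possible)
            )
        assert dls[1] <= dls[0] + 1e-9


class TestApplyRules:
    def _reference_ruleset(self) -> RuleSet:
        """A fixed reference decision list in the shape this pipeline
        emits: eight threshold rules for the non-diabetic class over real
        Entrez gene ids, plus the terminal diabetic default."""
        nd = "Non-diabetes"
        rules = [
            Rule([Condition("100128906", ">=", 2.7722),
                  Condition("326307", "<=", 15.2306),
                  Condition("8781", ">=", 0.0965),
                  Condition("100873065", "<=", 0.1036)], nd),
            Rule([Condition("100462954", ">=", 2.0984),
                  Condition("1487", "<=", 17.3460),
                  Condition("326307", "<=", 6.2868),
                  Condition("100873254", ">=", 3.0364)], nd),
            Rule([Condition("100128906", ">=", 49.6340),
                  Condition("143244", ">=", 1.0987),
                  Condition("486", "<=", 152.8666),
                  Condition("326307", "<=", 11.3894),
                  Condition("6126", "<=", 103.5050)], nd),
            Rule([Condition("100128906", ">=", 3.0256),
                  Condition("326307", "<=", 22.4381),
                  Condition("100128906", ">=", 225.8732),
                  Condition("388147", "<=", 50.3934),
                  Condition("100271332", ">=", 1.7952),
                  Condition("222901", "<=", 2.6067)], nd),
            Rule([Condition("100652939", ">=", 450.8125),
                  Condition("4574", "<=", 445.4115),
                  Condition("1487", "<=", 37.6438)], nd),
            Rule([Condition("285045", "<=", 0.0930),
                  Condition("100873254", "<=", 28.2479),
                  Condition("653147", ">=", 5.1856),
                  Condition("285900", ">=", 0.4760),
                  Condition("643932", ">=", 5.5063)], nd),
            Rule([Condition("100128906", ">=", 3.0256),
                  Condition("440737", ">=", 4.118),
                  Condition("100271003", ">=", 9.0166)], nd),
            Rule([Condition("100128906", ">=", 109.2232),
                  Condition("100873254", "<=", 28.3353),
                  Condition("644972", ">=", 53.5552),
                  Condition("644604", "<=", 7.9556)], nd),
        ]
        return RuleSet(rules=rules, default_class="Diabetes")

    def _cell(self, overrides: dict[str, float]) -> ExpressionDataset:
        genes = ["100128906", "326307", "8781", "100873065", "100462954",
                 "1487", "100873254", "143244", "486", "6126", "388147",
                 "100271332", "222901", "100652939", "4574", "285045",
                 "653147", "285900", "643932", "440737", "100271003",
                 "644972", "644604"]
        row = np.array([[overrides.get(g, 0.0) for g in genes]])
        return ExpressionDataset(values=row, gene_ids=genes, cell_ids=["cell1"])

    def test_first_rule_matches_the_published_example_cell(self):
        rs = self._reference_ruleset()
        cell = self._cell({"100128906": 3.0, "326307": 10.0,
                           "8781": 0.10, "100873065": 0.05})
        assert apply_rules(rs, cell)[0] == "Non-diabetes"

    def test_cell_failing_all_rule_bodies_falls_to_default(self):
        rs = self._reference_ruleset()
        cell = self._cell({"285045": 1.0})  # fails rule 6's first condition too
        assert apply_rules(rs, cell)[0] == "Diabetes"

    def test_empty_ruleset_predicts_default_for_everyone(self):
        rs = RuleSet(rules=[], default_class="D")
        cell = self._cell({})
        assert apply_rules(rs, cell)[0] == "D"

    def test_rule_order_matters_on_overlapping_rules(self):
        genes = ["gX"]
        cell = ExpressionDataset(values=np.array([[5.0]]), gene_ids=genes,
                                 cell_ids=["c"])
        r1 = Rule([Condition("gX", ">=", 1.0)], "A")
        r2 = Rule([Condition("gX", ">=", 2.0)], "B")
        assert apply_rules(RuleSet([r1, r2], "C"), cell)[0] == "A"
        assert apply_rules(RuleSet([r2, r1], "C"), cell)[0] == "B"

    def test_missing_gene_column_named_in_error(self):
        rs = RuleSet([Rule([Condition("absent", ">=", 1.0)], "A")], "B")
        cell = self._cell({})
        with pytest.raises(KeyError, match="absent"):
            apply_rules(rs, cell)


class TestEvaluateRules:
    def test_noiseless_planted_benchmark_scores_f1_one(self, planted_dataset):
        ds, truth = planted_dataset
        genes = [g["gene_id"] for g in truth["rule_genes"]] + ds.gene_ids[10:14]
        cv = evaluate_rules(ds, genes, RipperParams(seed=0),
                            cv_k=5, repeats=1, seed=1)
        assert cv.pooled.F1 == 1.0

    def test_fit_bookkeeping_counts_every_fold(self, planted_dataset):
        ds, truth = planted_dataset
        genes = [g["gene_id"] for g in truth["rule_genes"]]
        log: list = []
        evaluate_rules(ds, genes, RipperParams(seed=0), cv_k=5, repeats=2,
                       seed=1, fit_log=log)
        assert len(log) == 10
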