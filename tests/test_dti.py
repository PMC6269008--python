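"""Tree induction: impurity/chi-square primitives, CART and CHAID growth,
published decision rules, serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bbbperm.dti import (
    CLASS_NEG,
    CLASS_POS,
    DecisionTreeModel,
    InductionParams,
    PublishedRuleUndefined,
    best_cart_split,
    chi_square_split_pvalue,
    deserialize_tree,
    gini_impurity,
    induce_cart,
    induce_chaid,
    predict_class,
    predict_frame,
    published_rule_classifier,
    serialize_tree,
    to_dot,
)
from tests.conftest import make_planted_frame


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected", [((10, 10), 0.5), ((7, 0), 0.0), ((3, 1), 0.375)]
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestChiSquare:
    def test_perfect_association(self):
        statistic, p = chi_square_split_pvalue(np.array([[10, 0], [0, 10]]))
        assert statistic == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_independence(self):
        statistic, p = chi_square_split_pvalue(np.array([[5, 5], [5, 5]]))
        assert statistic == 0.0 and p == 1.0

    def test_degenerate_single_row(self):
        _, p = chi_square_split_pvalue(np.array([[7, 3]]))
        assert p == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        table = rng.integers(0, 20, size=(4, 2)) + 1
        s1, _ = chi_square_split_pvalue(table)
        s2, _ = chi_square_split_pvalue(table[::-1])
        assert s1 == pytest.approx(s2)


def brute_force_cart_split(X, y, min_child):
    """Independent oracle: enumerate every attribute/midpoint pair."""
    parent = gini_impurity((int((y == 0).sum()), int((y == 1).sum())))
    n = len(y)
    best = None
    for attr in sorted(X.columns):
        uniq = np.unique(X[attr].to_numpy(dtype=float))
        for a, b in zip(uniq, uniq[1:]):
            t = (a + b) / 2
            left = X[attr].to_numpy(dtype=float) < t
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_child or nr < min_child:
                continue
            gl = gini_impurity((int((y[left] == 0).sum()), int((y[left] == 1).sum())))
            gr = gini_impurity((int((y[~left] == 0).sum()), int((y[~left] == 1).sum())))
            gain = parent - (nl / n * gl + nr / n * gr)
            if best is None or gain > best[2] + 1e-12:
                best = (attr, t, gain)
    if best is None or best[2] <= 1e-12:
        return None
    return best


class TestCart:
    def test_four_point_textbook_split(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = np.array([CLASS_NEG, CLASS_NEG, CLASS_POS, CLASS_POS])
        params = InductionParams(paradigm="CART", min_parent=2, min_child=1)
        model = induce_cart(X, y, params)
        assert model.root.split_attr == "x"
        assert model.root.split_spec["threshold"] == pytest.approx(2.5)
        assert all(gini_impurity(c.class_counts) == 0.0 for c in model.root.children)

    def test_tie_breaks_to_lexicographically_first_attribute(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        X = pd.DataFrame({"b_attr": values, "a_attr": values})
        y = np.array([0, 0, 0, 1, 1, 1])
        split = best_cart_split(X, y, min_child=1)
        assert split[0] == "a_attr"

    def test_min_child_blocks_unbalanced_split(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.array([0] * 9 + [1])
        model = induce_cart(X, y, InductionParams(paradigm="CART"))

        def check(node):
            if not node.is_leaf:
                for child in node.children:
                    assert child.n_instances >= 5
                    check(child)

        check(model.root)

    @pytest.mark.parametrize("seed", range(5))
    def test_split_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        X = pd.DataFrame(
            {
                "u": rng.integers(0, 8, n).astype(float),
                "v": rng.normal(size=n).round(1),
                "w": rng.uniform(0, 5, n).round(2),
            }
        )
        y = rng.integers(0, 2, n)
        mine = best_cart_split(X, y, min_child=5)
        oracle = brute_force_cart_split(X, y, min_child=5)
        if oracle is None:
            assert mine is None
        else:
            assert mine[0] == oracle[0]
            assert mine[1] == pytest.approx(oracle[1])
            assert mine[2] == pytest.approx(oracle[2])

    def test_root_split_agrees_with_sklearn(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(3)
        X, y = make_planted_frame(80, rng, noise=0.1)
        clf = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", max_depth=1, random_state=0
        ).fit(X, y)
        model = induce_cart(
            X, y, InductionParams(paradigm="CART", max_depth=1, min_child=1, min_parent=2)
        )
        assert X.columns[clf.tree_.feature[0]] == model.root.split_attr
        assert clf.tree_.threshold[0] == pytest.approx(
            model.root.split_spec["threshold"], abs=1e-6
        )

    def test_pure_input_single_leaf(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        y = np.zeros(20, dtype=int)
        model = induce_cart(X, y, InductionParams(paradigm="CART"))
        assert model.root.is_leaf and model.root.leaf_class == CLASS_NEG

    def test_determinism(self):
        rng = np.random.default_rng(9)
        X, y = make_planted_frame(60, rng, noise=0.2)
        p = InductionParams(paradigm="CART")
        assert serialize_tree(induce_cart(X, y, p)) == serialize_tree(induce_cart(X, y, p))


class TestChaid:
    def test_perfect_separator_found_at_root(self):
        rng = np.random.default_rng(4)
        X, y = make_planted_frame(100, rng)
        model = induce_chaid(X, y, InductionParams(paradigm="CHAID"))
        assert model.root.split_attr == "sig"
        assert model.depth() == 1

    def test_root_recovery_rate_under_label_noise(self):
        # planted single-attribute rule, 5% label noise, 100 replicates
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X, y = make_planted_frame(120, rng, noise=0.05)
            model = induce_chaid(X, y, InductionParams(paradigm="CHAID"))
            hits += model.root.split_attr == "sig"
        assert hits >= 95

    def test_max_depth_honored(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        model = induce_chaid(Xc, y, InductionParams(paradigm="CHAID", max_depth=3))
        assert model.depth() <= 3

    def test_pure_input_single_leaf(self):
        X = pd.DataFrame({"x": np.arange(30.0)})
        y = np.ones(30, dtype=int)
        model = induce_chaid(X, y, InductionParams(paradigm="CHAID"))
        assert model.root.is_leaf and model.root.leaf_class == CLASS_POS

    def test_constant_attributes_yield_single_leaf(self):
        X = pd.DataFrame({"x": np.ones(40)})
        y = np.array([0, 1] * 20)
        model = induce_chaid(X, y, InductionParams(paradigm="CHAID"))
        assert model.root.is_leaf

    def test_child_sizes_respect_min_child(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        model = induce_chaid(Xc, y, InductionParams(paradigm="CHAID"))

        def check(node):
            for child in node.children:
                assert child.n_instances >= 5
                check(child)

        check(model.root)

    def test_determinism(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        p = InductionParams(paradigm="CHAID")
        assert serialize_tree(induce_chaid(Xc, y, p)) == serialize_tree(
            induce_chaid(Xc, y, p)
        )


class TestPrediction:
    def test_single_leaf_tree_predicts_its_class(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        model = induce_cart(X, np.zeros(20, dtype=int), InductionParams(paradigm="CART"))
        assert predict_class(model, {"x": 999.0}) == CLASS_NEG

    def test_missing_attribute_named_in_error(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        model = induce_cart(Xc, y, InductionParams(paradigm="CART"))
        row = {c: 1.0 for c in Xc.columns if c != model.root.split_attr}
        with pytest.raises(KeyError, match=model.root.split_attr):
            predict_class(model, row)


class TestPublishedRules:
    def test_table3_predictions(self, table3_rows):
        for paradigm in ("CHAID", "CART"):
            model = published_rule_classifier(paradigm)
            assert predict_class(model, table3_rows["sucrose"]) == CLASS_NEG
            assert predict_class(model, table3_rows["midazolam"]) == CLASS_POS

    def test_chaid_boundary_is_strict_less_than(self):
        model = published_rule_classifier("CHAID")
        # exactly at the printed threshold: not "less than", so the compound
        # falls through to the H-bond-acceptor criterion
        row = {"aLogP": -1.0028, "hBondAcceptors": 2}
        assert predict_class(model, row) == CLASS_POS

    def test_cart_high_tpsa_blocks_permeation(self):
        model = published_rule_classifier("CART")
        assert predict_class(model, {"aLogP": 1.0, "tPSA": 200.0}) == CLASS_NEG

    def test_unspecified_branch_raises(self):
        model = published_rule_classifier("CHAID")
        with pytest.raises(PublishedRuleUndefined):
            predict_class(model, {"aLogP": 0.5, "hBondAcceptors": 10})

    def test_published_chaid_depth_within_protocol(self):
        model = published_rule_classifier("CHAID")
        assert model.depth() <= 3


class TestSerialization:
    def test_round_trip_byte_identical(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        model = induce_chaid(Xc, y, InductionParams(paradigm="CHAID"))
        doc = serialize_tree(model)
        assert serialize_tree(deserialize_tree(doc)) == doc

    def test_round_trip_preserves_predictions(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        model = induce_cart(Xc, y, InductionParams(paradigm="CART"))
        restored = deserialize_tree(serialize_tree(model))
        assert np.array_equal(predict_frame(model, Xc), predict_frame(restored, Xc))

    def test_child_count_mismatch_rejected(self, synthetic_default):
        import json

        _, _, _, _, Xc, y = synthetic_default
        model = induce_cart(Xc, y, InductionParams(paradigm="CART"))
        doc = json.loads(serialize_tree(model))
        assert "children" in doc["root"], "fixture tree must have a split"
        doc["root"]["children"][0]["n_instances"] += 1
        with pytest.raises(ValueError, match="sum"):
            deserialize_tree(json.dumps(doc))

    def test_malformed_document_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            deserialize_tree("{not json")

    def test_dot_export_mentions_split_attributes(self, synthetic_default):
        _, _, _, _, Xc, y = synthetic_default
        model = induce_cart(Xc, y, InductionParams(paradigm="CART"))
        dot = to_dot(model)
        assert dot.startswith("digraph") and model.root.split_attr in dot
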