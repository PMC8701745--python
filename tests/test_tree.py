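"""Decision-tree induction, specialization calculus, census, serialization."""
import itertools

import numpy as np
import pandas as pd
import pytest

from dcmpanel.containers import ExpressionMatrix
from dcmpanel.errors import FormatError, InputError, ParameterError
from dcmpanel.tree import (
    DecisionTree,
    Leaf,
    Split,
    census,
    fit_tree,
    is_specialization,
    parse_tree,
    predict,
    serialize_tree,
    simplest_dyadic_in,
    trees_equal,
)


def _expr(rows, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(rows, dtype=float), index=genes, columns=samples)
    )


def _labels(labels, samples):
    return pd.Series(labels, index=samples)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def gini_gain_oracle(values: np.ndarray, y: np.ndarray) -> float:
    """Max Gini impurity decrease over every (gene, threshold) split."""

    def gini(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return 1.0 - (p**2).sum()

    n, n_genes = values.shape
    parent = gini(y)
    best = 0.0
    for g in range(n_genes):
        v = values[:, g]
        for t in np.unique(v)[:-1]:
            left = y[v <= t]
            right = y[v > t]
            gain = parent - len(left) / n * gini(left) - len(right) / n * gini(right)
            best = max(best, gain)
    return best


def _single_split_gain(v, y, threshold):
    def gini(labels):
        n = len(labels)
        if n == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return 1.0 - (p**2).sum()

    n = len(y)
    left, right = y[v <= threshold], y[v > threshold]
    return gini(y) - len(left) / n * gini(left) - len(right) / n * gini(right)


def collapse_oracle(fine: DecisionTree, coarse: DecisionTree) -> bool:
    """Enumerate every subset of internal nodes of ``fine`` to collapse."""

    def internal_nodes(node, path=()):
        if isinstance(node, Leaf):
            return []
        out = [path]
        out += internal_nodes(node.left, path + ("L",))
        out += internal_nodes(node.right, path + ("R",))
        return out

    def subtree_majority(node):
        totals = {}

        def walk(n):
            if isinstance(n, Leaf):
                for k, v in n.support.items():
                    totals[k] = totals.get(k, 0) + v
            else:
                walk(n.left)
                walk(n.right)

        walk(node)
        ranked = sorted(totals.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return None
        return ranked[0][0] if ranked else None

    def collapse(node, subset, path=()):
        if isinstance(node, Leaf):
            return node
        if path in subset:
            label = subtree_majority(node)
            if label is None:
                return None  # collapse not allowed here
            return Leaf(label=label, support={})
        left = collapse(node.left, subset, path + ("L",))
        right = collapse(node.right, subset, path + ("R",))
        if left is None or right is None:
            return None
        return Split(node.gene, node.threshold, left, right)

    def same(a, b):
        if isinstance(a, Leaf) and isinstance(b, Leaf):
            return a.label == b.label
        if isinstance(a, Split) and isinstance(b, Split):
            return (
                a.gene == b.gene
                and abs(a.threshold - b.threshold) <= 1e-9
                and same(a.left, b.left)
                and same(a.right, b.right)
            )
        return False

    nodes = internal_nodes(fine.root)
    for r in range(len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            collapsed = collapse(fine.root, set(subset))
            if collapsed is not None and same(collapsed, coarse.root):
                return True
    return False


def random_tree(rng, depth, genes=("gA", "gB", "gC")) -> DecisionTree:
    def build(d):
        if d == 0 or rng.random() < 0.35:
            counts = {"DCM": int(rng.integers(0, 6)), "HS": int(rng.integers(0, 6))}
            if counts["DCM"] == counts["HS"]:
                counts["DCM"] += 1
            label = "DCM" if counts["DCM"] > counts["HS"] else "HS"
            return Leaf(label=label, support=counts)
        return Split(
            gene=str(rng.choice(genes)),
            threshold=float(np.round(rng.uniform(0, 10), 3)),
            left=build(d - 1),
            right=build(d - 1),
        )

    root = build(depth)
    if isinstance(root, Leaf):
        root = Split(gene=genes[0], threshold=5.0, left=root, right=build(0))
    return DecisionTree(root=root)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitTree:
    def test_pure_training_set_is_single_leaf(self):
        expr = _expr([[1, 2, 3]], ["gA"], ["a", "b", "c"])
        tree = fit_tree(expr, _labels(["HS"] * 3, ["a", "b", "c"]), ["gA"])
        assert isinstance(tree.root, Leaf)
        assert tree.root.label == "HS"

    def test_max_margin_midpoint_example(self):
        # class values {1,2} vs {6,8}: the widest consistent gap is (2,6)
        # and the stable threshold lands on 4.0
        expr = _expr([[1, 2, 6, 8]], ["gA"], list("abcd"))
        labels = _labels(["DCM", "DCM", "HS", "HS"], list("abcd"))
        tree = fit_tree(expr, labels, ["gA"], criterion="stable")
        assert isinstance(tree.root, Split)
        assert tree.root.threshold == pytest.approx(4.0)
        assert tree.depth() == 1
        assert tree.root.left.label == "DCM"

    def test_stability_prior_breaks_gain_ties(self):
        # two genes separate perfectly; the higher-frequency one wins
        expr = _expr(
            [[1, 2, 6, 8], [1, 2, 6, 8]], ["g1", "g2"], list("abcd")
        )
        labels = _labels(["DCM", "DCM", "HS", "HS"], list("abcd"))
        tree = fit_tree(
            expr,
            labels,
            ["g2", "g1"],
            criterion="stable",
            stability_prior={"g1": 1.0, "g2": 0.8},
        )
        assert tree.root.gene == "g1"

    def test_empty_candidates_rejected(self):
        expr = _expr([[1, 2]], ["gA"], ["a", "b"])
        with pytest.raises(ParameterError):
            fit_tree(expr, _labels(["DCM", "HS"], ["a", "b"]), [])

    def test_standard_root_matches_exhaustive_enumeration(self):
        # the standard criterion attains the oracle's best root gain on
        # many random small datasets
        rng = np.random.default_rng(123)
        for _ in range(150):
            n = int(rng.integers(4, 9))
            n_genes = int(rng.integers(1, 5))
            values = rng.integers(0, 6, size=(n, n_genes)).astype(float)
            y = rng.choice(["DCM", "HS"], size=n)
            if len(set(y)) < 2:
                y[0] = "DCM" if y[1] == "HS" else "HS"
            genes = [f"g{i}" for i in range(n_genes)]
            samples = [f"s{i}" for i in range(n)]
            expr = _expr(values.T, genes, samples)
            tree = fit_tree(
                expr, _labels(y, samples), genes, criterion="standard", min_leaf=1
            )
            oracle_best = gini_gain_oracle(values, y)
            if isinstance(tree.root, Leaf):
                assert oracle_best <= 1e-12
            else:
                got = _single_split_gain(
                    values[:, genes.index(tree.root.gene)], y, tree.root.threshold
                )
                assert got == pytest.approx(oracle_best, abs=1e-12)

    def test_stable_root_attains_oracle_gain_too(self):
        rng = np.random.default_rng(321)
        for _ in range(80):
            n = int(rng.integers(4, 9))
            values = rng.integers(0, 6, size=(n, 3)).astype(float)
            y = rng.choice(["DCM", "HS"], size=n)
            if len(set(y)) < 2:
                y[0] = "DCM" if y[1] == "HS" else "HS"
            genes = ["g0", "g1", "g2"]
            samples = [f"s{i}" for i in range(n)]
            expr = _expr(values.T, genes, samples)
            tree = fit_tree(
                expr, _labels(y, samples), genes, criterion="stable", min_leaf=1
            )
            oracle_best = gini_gain_oracle(values, y)
            if isinstance(tree.root, Split):
                got = _single_split_gain(
                    values[:, genes.index(tree.root.gene)], y, tree.root.threshold
                )
                assert got == pytest.approx(oracle_best, abs=1e-12)


class TestPredict:
    def test_single_leaf_predicts_its_label(self):
        tree = DecisionTree(root=Leaf("HS", {"HS": 3, "DCM": 0}))
        assert predict(tree, {"gA": 123.0}) == "HS"

    def test_boundary_goes_left(self):
        tree = DecisionTree(
            root=Split("gA", 4.0, Leaf("DCM", {"DCM": 2}), Leaf("HS", {"HS": 2}))
        )
        assert predict(tree, {"gA": 4.0}) == "DCM"
        assert predict(tree, {"gA": 4.0001}) == "HS"

    def test_missing_gene_rejected(self):
        tree = DecisionTree(
            root=Split("gA", 4.0, Leaf("DCM", {"DCM": 2}), Leaf("HS", {"HS": 2}))
        )
        with pytest.raises(InputError):
            predict(tree, {"gB": 1.0})


class TestSpecialization:
    def test_reflexive(self):
        rng = np.random.default_rng(1)
        t = random_tree(rng, 3)
        assert is_specialization(t, t)

    def test_single_collapse(self):
        fine = DecisionTree(
            root=Split(
                "gA",
                4.0,
                Split("gB", 2.0, Leaf("DCM", {"DCM": 3}), Leaf("HS", {"HS": 1, "DCM": 2})),
                Leaf("HS", {"HS": 4}),
            )
        )
        coarse = DecisionTree(
            root=Split("gA", 4.0, Leaf("DCM", {"DCM": 5, "HS": 1}), Leaf("HS", {"HS": 4}))
        )
        assert is_specialization(fine, coarse)
        assert not is_specialization(coarse, fine)

    def test_different_root_genes_unrelated(self):
        a = DecisionTree(root=Split("gA", 1.0, Leaf("DCM", {"DCM": 2}), Leaf("HS", {"HS": 2})))
        b = DecisionTree(root=Split("gB", 1.0, Leaf("DCM", {"DCM": 2}), Leaf("HS", {"HS": 2})))
        assert not is_specialization(a, b)

    def test_agrees_with_collapse_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        agree = 0
        for _ in range(200):
            a = random_tree(rng, int(rng.integers(1, 4)))
            b = random_tree(rng, int(rng.integers(1, 4)))
            assert is_specialization(a, b) == collapse_oracle(a, b)
            agree += 1
        assert agree == 200


class TestCensus:
    def test_identical_trees_form_one_class(self):
        rng = np.random.default_rng(2)
        t = random_tree(rng, 2)
        c = census([t] * 22)
        assert c.n_types == 1
        assert c.edges == ()

    def test_copy_plus_refinement_gives_edge(self):
        coarse = DecisionTree(
            root=Split("gA", 4.0, Leaf("DCM", {"DCM": 5, "HS": 1}), Leaf("HS", {"HS": 4}))
        )
        fine = DecisionTree(
            root=Split(
                "gA",
                4.0,
                Split("gB", 2.0, Leaf("DCM", {"DCM": 3}), Leaf("HS", {"HS": 1, "DCM": 2})),
                Leaf("HS", {"HS": 4}),
            )
        )
        c = census([coarse] * 21 + [fine])
        assert c.n_types == 2
        assert (1, 0) in c.edges  # the refinement specializes the majority type

    def test_distinct_random_trees_all_separate(self):
        rng = np.random.default_rng(3)
        trees = []
        while len(trees) < 6:
            t = random_tree(rng, 2)
            if all(not trees_equal(t, u) for u in trees):
                trees.append(t)
        c = census(trees)
        assert c.n_types == 6
        for i, j in c.edges:
            assert collapse_oracle(trees[c.classes[i][0]], trees[c.classes[j][0]])


class TestSerialization:
    def test_round_trip_on_random_trees(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            t = random_tree(rng, int(rng.integers(0, 5)))
            assert trees_equal(parse_tree(serialize_tree(t)), t)

    def test_single_leaf_form(self):
        t = DecisionTree(root=Leaf("DCM", {"DCM": 4, "HS": 0}))
        text = serialize_tree(t)
        assert '"type": "leaf"' in text
        back = parse_tree(text)
        assert back.root.support == {"DCM": 4, "HS": 0}

    def test_full_precision_threshold_round_trip(self):
        t = DecisionTree(
            root=Split("gA", 0.1 + 0.2, Leaf("DCM", {"DCM": 1}), Leaf("HS", {"HS": 1}))
        )
        back = parse_tree(serialize_tree(t))
        assert back.root.threshold == t.root.threshold

    def test_malformed_text_error_carries_path(self):
        bad = '{"type": "split", "gene": "gA", "threshold": "1.0", "left": {"type": "leaf", "label": "DCM", "support": {}}, "right": {"bogus": 1}}'
        with pytest.raises(FormatError, match=r"\$/right"):
            parse_tree(bad)

    def test_non_json_rejected(self):
        with pytest.raises(FormatError):
            parse_tree("not json at all")


class TestSimplestDyadic:
    def test_worked_example(self):
        assert simplest_dyadic_in(2.0, 6.0) == 4.0

    def test_value_lies_strictly_inside(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = float(rng.uniform(-50, 50))
            b = a + float(rng.uniform(1e-6, 20))
            t = simplest_dyadic_in(a, b)
            assert a < t < b

    def test_prefers_coarser_values(self):
        assert simplest_dyadic_in(9.7, 10.9) == 10.0
        assert simplest_dyadic_in(10.06, 10.55) == 10.5
        assert simplest_dyadic_in(-0.3, 0.2) == 0.0
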