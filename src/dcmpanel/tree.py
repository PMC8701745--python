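"""Binary axis-aligned decision trees with a stability-oriented criterion.

Two splitting criteria are provided, both maximizing Gini impurity
decrease over (gene, threshold) candidates:

* ``standard`` — CART-like: candidate thresholds at every midpoint of
  adjacent distinct values; ties in gain broken by data order (first
  candidate gene, then lowest threshold).  Deliberately order-sensitive,
  so leave-one-out folds typically produce many distinct trees.

* ``stable`` — designed so that near-identical training sets yield
  bit-identical trees.  The split partition is still chosen by maximal
  Gini gain, but (1) the threshold is placed inside the widest value gap
  ("margin") realizing the optimal partition, at the *simplest dyadic
  value* m·2^j (largest 2^j, nearest the gap midpoint) strictly inside
  that gap — removing or perturbing a single sample usually leaves this
  snapped threshold unchanged, whereas a raw midpoint always moves when
  a gap-boundary sample is dropped; (2) ties in gain are broken by the
  higher selection-frequency prior, then the lexicographically smaller
  gene id, then the wider margin — sample-invariant keys outrank the
  noise-sensitive margin so that near-identical folds agree on the split
  gene; (3) callers are expected to restrict candidate genes to the
  cross-fold stability panel.

Leaves carry majority labels with training support counts; ties go to
"DCM" (logged).  The specialization calculus formalizes "tree B is a
coarsening of tree A": B is obtained from A by collapsing some subtrees
to leaves labeled with the subtree's strict support-weighted majority.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: absolute tolerance for threshold equality in the census
THRESHOLD_TOL = 1e-9
#: tolerance for comparing Gini gains
GAIN_TOL = 1e-12

TIE_LABEL = "DCM"


@dataclass(frozen=True)
class Leaf:
    label: str
    support: Mapping[str, int]  # training class counts at the leaf


@dataclass(frozen=True)
class Split:
    gene: str
    threshold: float
    left: "Node"  # value <= threshold
    right: "Node"  # value > threshold


Node = Union[Leaf, Split]


@dataclass(frozen=True)
class DecisionTree:
    root: Node

    def depth(self) -> int:
        def _d(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def n_internal(self) -> int:
        def _c(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + _c(node.left) + _c(node.right)

        return _c(self.root)

    def genes_used(self) -> set[str]:
        out: set[str] = set()

        def _walk(node: Node) -> None:
            if isinstance(node, Split):
                out.add(node.gene)
                _walk(node.left)
                _walk(node.right)

        _walk(self.root)
        return out


# ---------------------------------------------------------------------------
# threshold placement
# ---------------------------------------------------------------------------


def simplest_dyadic_in(a: float, b: float) -> float:
    """The coarsest dyadic value m*2^j strictly inside (a, b).

    Among values at the coarsest resolution that fits, the one nearest
    the midpoint wins (ties toward the smaller value).  Falls back to the
    midpoint for degenerate intervals.
    """
    if not a < b:
        raise ParameterError(f"need a < b, got ({a}, {b})")
    mid = (a + b) / 2.0
    for j in range(32, -60, -1):
        step = 2.0**j
        lo = math.floor(a / step) + 1
        hi = math.ceil(b / step) - 1
        if lo > hi:
            continue
        candidates = [m * step for m in range(lo, hi + 1)]
        candidates = [c for c in candidates if a < c < b]
        if candidates:
            return min(candidates, key=lambda c: (abs(c - mid), c))
    return mid


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _candidate_splits(values: np.ndarray, y: np.ndarray, n_classes: int):
    """Yield (gain, boundary_low, boundary_high) for one gene at a node.

    ``values`` are the gene's training values, ``y`` integer class codes.
    A boundary sits between adjacent distinct sorted values; the gain is
    the Gini impurity decrease of the induced partition.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    labels = y[order]
    n = len(v)
    total = np.bincount(labels, minlength=n_classes).astype(float)
    parent = _gini(total)
    left = np.zeros(n_classes)
    out = []
    for i in range(n - 1):
        left[labels[i]] += 1
        if v[i + 1] <= v[i]:
            continue
        right = total - left
        n_left = i + 1
        n_right = n - n_left
        gain = parent - (n_left / n) * _gini(left) - (n_right / n) * _gini(right)
        out.append((gain, float(v[i]), float(v[i + 1])))
    return out


def fit_tree(
    expr: ExpressionMatrix,
    labels: pd.Series,
    candidate_genes: Sequence[str],
    criterion: str = "stable",
    stability_prior=None,
    max_depth: int = 3,
    min_leaf: int = 2,
) -> DecisionTree:
    """Recursive partitioning of samples by gene-expression thresholds.

    ``expr`` holds the training samples (genes x samples); ``labels``
    maps sample id to class.  ``stability_prior`` is a FrequencyTable (or
    gene -> frequency mapping) consulted by the ``stable`` criterion's
    tie-break.  A node becomes a leaf when it is pure, at ``max_depth``,
    has fewer than ``min_leaf`` samples, or no split improves impurity.
    """
    candidate_genes = [str(g) for g in candidate_genes]
    if not candidate_genes:
        raise ParameterError("candidate gene set is empty")
    if criterion not in ("standard", "stable"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    unknown = [g for g in candidate_genes if g not in expr.frame.index]
    if unknown:
        raise InputError(f"candidate genes not in expression matrix: {unknown[:5]}")

    labels = labels.astype(str)
    missing = [s for s in expr.sample_ids if s not in labels.index]
    if missing:
        raise InputError(f"samples without a class label: {missing}")
    y_str = labels.loc[expr.sample_ids].to_numpy()
    classes = sorted(set(y_str))
    if len(classes) < 1:
        raise InputError("no samples to fit")
    class_code = {c: i for i, c in enumerate(classes)}
    y = np.array([class_code[c] for c in y_str])

    # samples x genes, in candidate order
    X = expr.frame.loc[candidate_genes].to_numpy(dtype=float).T

    if isinstance(stability_prior, dict):
        prior = dict(stability_prior)
    elif stability_prior is None:
        prior = {}
    else:  # FrequencyTable-like
        prior = stability_prior.frequencies

    def majority_leaf(idx: np.ndarray) -> Leaf:
        counts = np.bincount(y[idx], minlength=len(classes))
        support = {c: int(counts[class_code[c]]) for c in classes}
        best = counts.max()
        winners = [c for c in classes if counts[class_code[c]] == best]
        if len(winners) > 1:
            label = TIE_LABEL if TIE_LABEL in winners else min(winners)
            logger.info("leaf label tie %s -> %s", winners, label)
        else:
            label = winners[0]
        return Leaf(label=label, support=support)

    def choose_split(idx: np.ndarray):
        """Best (gene, threshold) at this node, or None."""
        best = None  # (gain, key..., gene, threshold)
        if criterion == "standard":
            best_gain = GAIN_TOL
            for gpos, gene in enumerate(candidate_genes):
                for gain, a, b in _candidate_splits(X[idx, gpos], y[idx], len(classes)):
                    if gain > best_gain + GAIN_TOL:
                        best_gain = gain
                        best = (gene, (a + b) / 2.0)
            return best
        # stable: collect all candidates at max gain, then tie-break
        entries = []  # (gain, gene, a, b)
        for gpos, gene in enumerate(candidate_genes):
            for gain, a, b in _candidate_splits(X[idx, gpos], y[idx], len(classes)):
                entries.append((gain, gene, a, b))
        if not entries:
            return None
        max_gain = max(e[0] for e in entries)
        if max_gain <= GAIN_TOL:
            return None
        tied = [e for e in entries if e[0] >= max_gain - GAIN_TOL]
        # higher prior frequency, then gene id, then wider margin, lower gap
        tied.sort(
            key=lambda e: (
                -prior.get(e[1], 0.0),
                e[1],
                -(e[3] - e[2]),
                e[2],
            )
        )
        _, gene, a, b = tied[0]
        return (gene, simplest_dyadic_in(a, b))

    gene_pos = {g: i for i, g in enumerate(candidate_genes)}

    def build(idx: np.ndarray, depth: int) -> Node:
        node_classes = set(y[idx])
        if (
            len(node_classes) == 1
            or depth >= max_depth
            or len(idx) < min_leaf
        ):
            return majority_leaf(idx)
        chosen = choose_split(idx)
        if chosen is None:
            return majority_leaf(idx)
        gene, threshold = chosen
        values = X[idx, gene_pos[gene]]
        left_mask = values <= threshold
        left = build(idx[left_mask], depth + 1)
        right = build(idx[~left_mask], depth + 1)
        return Split(gene=gene, threshold=float(threshold), left=left, right=right)

    root = build(np.arange(len(y)), 0)
    return DecisionTree(root=root)


def predict(tree: DecisionTree, sample: Mapping[str, float]) -> str:
    """Deterministic root-to-leaf descent; value <= threshold goes left."""
    node = tree.root
    while isinstance(node, Split):
        if node.gene not in sample:
            raise InputError(f"sample has no value for gene {node.gene!r}")
        node = node.left if sample[node.gene] <= node.threshold else node.right
    return node.label


# ---------------------------------------------------------------------------
# equality, specialization, census
# ---------------------------------------------------------------------------


def trees_equal(a: DecisionTree, b: DecisionTree, tol: float = THRESHOLD_TOL) -> bool:
    """Node-for-node identity of structure, genes, thresholds and labels."""

    def _eq(x: Node, z: Node) -> bool:
        if isinstance(x, Leaf) and isinstance(z, Leaf):
            return x.label == z.label
        if isinstance(x, Split) and isinstance(z, Split):
            return (
                x.gene == z.gene
                and abs(x.threshold - z.threshold) <= tol
                and _eq(x.left, z.left)
                and _eq(x.right, z.right)
            )
        return False

    return _eq(a.root, b.root)


def _strict_majority_label(node: Node) -> str | None:
    """Support-weighted strict majority over a subtree's leaves, or None."""
    totals: dict[str, int] = {}

    def _walk(n: Node) -> None:
        if isinstance(n, Leaf):
            for label, count in n.support.items():
                totals[label] = totals.get(label, 0) + int(count)
        else:
            _walk(n.left)
            _walk(n.right)

    _walk(node)
    ranked = sorted(totals.items(), key=lambda kv: -kv[1])
    if not ranked:
        return None
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def is_specialization(
    t_fine: DecisionTree, t_coarse: DecisionTree, tol: float = THRESHOLD_TOL
) -> bool:
    """True iff collapsing some subtrees of ``t_fine`` yields ``t_coarse``.

    A collapsed subtree becomes a leaf labeled with its strict
    support-weighted majority label (no strict majority means it cannot
    be collapsed).  Equality counts as specialization (empty collapse).
    """

    def _match(fine: Node, coarse: Node) -> bool:
        if isinstance(coarse, Leaf):
            if isinstance(fine, Leaf):
                return fine.label == coarse.label
            maj = _strict_majority_label(fine)
            return maj is not None and maj == coarse.label
        if isinstance(fine, Leaf):
            return False
        return (
            fine.gene == coarse.gene
            and abs(fine.threshold - coarse.threshold) <= tol
            and _match(fine.left, coarse.left)
            and _match(fine.right, coarse.right)
        )

    return _match(t_fine.root, t_coarse.root)


@dataclass(frozen=True)
class TreeCensus:
    """Equality classes of a tree family and their specialization edges.

    ``classes`` lists member indices per equality class (in first-seen
    order); ``edges`` holds (fine, coarse) class-index pairs where the
    first class's representative specializes the second's.
    """

    classes: tuple[tuple[int, ...], ...]
    edges: tuple[tuple[int, int], ...]

    @property
    def n_types(self) -> int:
        return len(self.classes)

    def to_dict(self) -> dict:
        return {
            "n_types": self.n_types,
            "classes": [list(c) for c in self.classes],
            "specialization_edges": [list(e) for e in self.edges],
        }


def census(trees: Sequence[DecisionTree], tol: float = THRESHOLD_TOL) -> TreeCensus:
    """Partition trees into equality classes and relate them by specialization."""
    if not trees:
        raise InputError("census needs at least one tree")
    reps: list[int] = []
    classes: list[list[int]] = []
    for i, tree in enumerate(trees):
        for ci, rep in enumerate(reps):
            if trees_equal(tree, trees[rep], tol):
                classes[ci].append(i)
                break
        else:
            reps.append(i)
            classes.append([i])
    edges = []
    for i, rep_i in enumerate(reps):
        for j, rep_j in enumerate(reps):
            if i != j and is_specialization(trees[rep_i], trees[rep_j], tol):
                edges.append((i, j))
    return TreeCensus(
        classes=tuple(tuple(c) for c in classes),
        edges=tuple(edges),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _node_to_obj(node: Node) -> dict:
    if isinstance(node, Leaf):
        return {
            "type": "leaf",
            "label": node.label,
            "support": {k: int(v) for k, v in sorted(node.support.items())},
        }
    return {
        "type": "split",
        "gene": node.gene,
        "threshold": repr(float(node.threshold)),
        "left": _node_to_obj(node.left),
        "right": _node_to_obj(node.right),
    }


def serialize_tree(tree: DecisionTree) -> str:
    """JSON text form; thresholds as full-precision decimal strings."""
    return json.dumps(_node_to_obj(tree.root), indent=2, sort_keys=True)


def _node_from_obj(obj, path: str) -> Node:
    if not isinstance(obj, dict) or "type" not in obj:
        raise FormatError(f"malformed tree node at {path}: expected an object with 'type'")
    if obj["type"] == "leaf":
        try:
            support = {str(k): int(v) for k, v in obj["support"].items()}
            return Leaf(label=str(obj["label"]), support=support)
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed leaf at {path}: {exc}") from exc
    if obj["type"] == "split":
        try:
            threshold = float(obj["threshold"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed threshold at {path}: {exc}") from exc
        if not math.isfinite(threshold):
            raise FormatError(f"non-finite threshold at {path}")
        for key in ("gene", "left", "right"):
            if key not in obj:
                raise FormatError(f"malformed split at {path}: missing {key!r}")
        return Split(
            gene=str(obj["gene"]),
            threshold=threshold,
            left=_node_from_obj(obj["left"], path + "/left"),
            right=_node_from_obj(obj["right"], path + "/right"),
        )
    raise FormatError(f"malformed tree node at {path}: unknown type {obj['type']!r}")


def parse_tree(text: str) -> DecisionTree:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"tree JSON does not parse: {exc}") from exc
    return DecisionTree(root=_node_from_obj(obj, "$"))
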