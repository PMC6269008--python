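"""Decision-tree induction for permeation classification (CHAID and CART).

Two classic paradigms are implemented from scratch:

* CART grows binary splits on continuous descriptors, choosing the
  attribute/threshold pair with the largest Gini-impurity decrease among
  midpoints of consecutive sorted unique values.
* CHAID first discretizes each continuous descriptor into quantile bins,
  iteratively merges adjacent bins whose class distributions are
  statistically indistinguishable (pairwise chi-square), and splits on the
  attribute with the smallest Bonferroni-adjusted chi-square p-value.

Class labels are encoded 0 = CNSp- (weak permeant), 1 = CNSp+ (strong
permeant); leaf ties predict CNSp- (conservative: assume non-penetration).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

CLASS_NEG = 0  # CNSp-
CLASS_POS = 1  # CNSp+
CLASS_NAMES = {CLASS_NEG: "CNSp-", CLASS_POS: "CNSp+"}


@dataclass
class InductionParams:
    """Growth and stopping parameters for tree induction.

    Defaults follow the published protocol: CHAID depth 3, CART depth 5,
    at least 10 instances in a parent node and 5 in each child.
    """

    paradigm: str = "CHAID"  # "CHAID" | "CART"
    max_depth: int | None = None
    min_parent: int = 10
    min_child: int = 5
    alpha_split: float = 0.05
    alpha_merge: float = 0.05
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.paradigm = self.paradigm.upper()
        if self.paradigm not in ("CHAID", "CART"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.max_depth is None:
            self.max_depth = 3 if self.paradigm == "CHAID" else 5
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_child > self.min_parent:
            raise ValueError("min_child must be <= min_parent")


class PublishedRuleUndefined(RuntimeError):
    """Routing reached a branch whose threshold the source text never prints."""


@dataclass
class TreeNode:
    """One node of an induced or published tree.

    Internal nodes carry a ``split_attr`` and a ``split_spec``; for CART the
    spec is ``{"kind": "threshold", "threshold": t, "op": "<"}`` with two
    children (op-true first), for CHAID ``{"kind": "intervals", "intervals":
    [(lo, hi], ...]}`` with one child per merged category interval.
    """

    n_instances: int
    class_counts: tuple[int, int]  # (n_neg, n_pos)
    split_attr: str | None = None
    split_spec: dict[str, Any] | None = None
    children: list["TreeNode"] = field(default_factory=list)
    leaf_class: int | None = None
    unspecified: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(child.depth() for child in self.children)


@dataclass
class DecisionTreeModel:
    """A decision tree plus the parameters and attribute names it uses."""

    root: TreeNode
    params: InductionParams
    attributes: tuple[str, ...]

    def depth(self) -> int:
        return self.root.depth()


def gini_impurity(class_counts: tuple[int, int]) -> float:
    """Gini impurity 1 - sum(p_i^2) of a two-class count pair; in [0, 0.5]."""
    total = sum(class_counts)
    if total <= 0:
        raise ValueError("empty node has no impurity")
    return 1.0 - sum((c / total) ** 2 for c in class_counts)


def chi_square_split_pvalue(contingency: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p for an r x 2 count table.

    df = (r - 1); a degenerate table (single row, or an empty class column)
    yields statistic 0 and p = 1.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    row_sums = table.sum(axis=1)
    table = table[row_sums > 0]
    r = table.shape[0]
    col_sums = table.sum(axis=0)
    if r < 2 or (col_sums == 0).any():
        return 0.0, 1.0
    total = table.sum()
    expected = np.outer(table.sum(axis=1), col_sums) / total
    statistic = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=r - 1))
    return statistic, p


def _majority_class(class_counts: tuple[int, int]) -> int:
    n_neg, n_pos = class_counts
    return CLASS_POS if n_pos > n_neg else CLASS_NEG  # tie -> CNSp-


def _counts(y: np.ndarray) -> tuple[int, int]:
    return int((y == CLASS_NEG).sum()), int((y == CLASS_POS).sum())


def _drop_missing(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray, int]:
    mask = ~X.isna().any(axis=1).to_numpy()
    return X.loc[mask], y[mask], int((~mask).sum())


# --------------------------------------------------------------------------
# CART
# --------------------------------------------------------------------------

def best_cart_split(
    X: pd.DataFrame, y: np.ndarray, min_child: int
) -> tuple[str, float, float] | None:
    """(attribute, threshold, gain) of the best Gini-gain binary split.

    Candidate thresholds are midpoints of consecutive sorted unique values;
    ties keep the lexicographically first attribute, then lowest threshold.
    """
    parent_gini = gini_impurity(_counts(y))
    n = len(y)
    best: tuple[str, float, float] | None = None
    for attr in sorted(X.columns):
        values = X[attr].to_numpy(dtype=float)
        order = np.argsort(values, kind="stable")
        v_sorted = values[order]
        y_sorted = y[order]
        uniq = np.unique(v_sorted)
        if len(uniq) < 2:
            continue
        # cumulative positive counts allow O(1) impurity per threshold
        cum_pos = np.cumsum(y_sorted == CLASS_POS)
        for k in range(len(uniq) - 1):
            threshold = 0.5 * (uniq[k] + uniq[k + 1])
            n_left = int(np.searchsorted(v_sorted, threshold, side="left"))
            n_right = n - n_left
            if n_left < min_child or n_right < min_child:
                continue
            pos_left = int(cum_pos[n_left - 1]) if n_left else 0
            left = (n_left - pos_left, pos_left)
            total_pos = int(cum_pos[-1])
            right = (n_right - (total_pos - pos_left), total_pos - pos_left)
            gain = parent_gini - (
                n_left / n * gini_impurity(left) + n_right / n * gini_impurity(right)
            )
            if best is None or gain > best[2] + 1e-12:
                best = (attr, float(threshold), float(gain))
    if best is None or best[2] <= 1e-12:
        return None
    return best


def _grow_cart(X: pd.DataFrame, y: np.ndarray, params: InductionParams, depth: int) -> TreeNode:
    counts = _counts(y)
    node = TreeNode(n_instances=len(y), class_counts=counts,
                    leaf_class=_majority_class(counts))
    if (
        depth >= params.max_depth
        or len(y) < params.min_parent
        or min(counts) == 0
    ):
        return node
    split = best_cart_split(X, y, params.min_child)
    if split is None:
        return node
    attr, threshold, _gain = split
    mask = X[attr].to_numpy(dtype=float) < threshold
    node.split_attr = attr
    node.split_spec = {"kind": "threshold", "threshold": threshold, "op": "<"}
    node.leaf_class = None
    node.children = [
        _grow_cart(X.loc[mask], y[mask], params, depth + 1),
        _grow_cart(X.loc[~mask], y[~mask], params, depth + 1),
    ]
    return node


def induce_cart(X: pd.DataFrame, y: np.ndarray, params: InductionParams) -> DecisionTreeModel:
    """Grow a binary CART tree by greedy Gini-gain splitting."""
    if params.paradigm != "CART":
        raise ValueError("params.paradigm must be CART")
    X, y, _dropped = _drop_missing(X, np.asarray(y))
    if len(y) == 0:
        raise ValueError("no complete rows to train on")
    root = _grow_cart(X, y, params, depth=0)
    return DecisionTreeModel(root=root, params=params, attributes=tuple(sorted(X.columns)))


# --------------------------------------------------------------------------
# CHAID
# --------------------------------------------------------------------------

def quantile_bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior edges of (at most) ``n_bins`` quantile bins over ``values``."""
    probs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(values, probs))
    return edges


def _merge_adjacent(
    groups: list[list[int]], cat_counts: np.ndarray, alpha_merge: float
) -> list[list[int]]:
    """Merge the most-similar adjacent category groups while their pairwise
    chi-square p exceeds ``alpha_merge``."""

    def group_counts(g: list[int]) -> np.ndarray:
        return cat_counts[g].sum(axis=0)

    while len(groups) > 1:
        best_pair, best_p = None, -1.0
        for i in range(len(groups) - 1):
            table = np.vstack([group_counts(groups[i]), group_counts(groups[i + 1])])
            _, p = chi_square_split_pvalue(table)
            if p > best_p:
                best_pair, best_p = i, p
        if best_p > alpha_merge and best_pair is not None:
            groups = (
                groups[:best_pair]
                + [groups[best_pair] + groups[best_pair + 1]]
                + groups[best_pair + 2:]
            )
        else:
            break
    return groups


def _enforce_min_child(
    groups: list[list[int]], cat_counts: np.ndarray, min_child: int
) -> list[list[int]]:
    """Force-merge undersized groups into their most-similar neighbour."""

    def size(g: list[int]) -> int:
        return int(cat_counts[g].sum())

    while len(groups) > 1 and min(size(g) for g in groups) < min_child:
        idx = min(range(len(groups)), key=lambda i: size(groups[i]))
        neighbours = [i for i in (idx - 1, idx + 1) if 0 <= i < len(groups)]
        best_nb, best_p = neighbours[0], -1.0
        for nb in neighbours:
            table = np.vstack(
                [cat_counts[groups[idx]].sum(axis=0), cat_counts[groups[nb]].sum(axis=0)]
            )
            _, p = chi_square_split_pvalue(table)
            if p > best_p:
                best_nb, best_p = nb, p
        lo, hi = sorted((idx, best_nb))
        groups = groups[:lo] + [groups[lo] + groups[hi]] + groups[hi + 1:]
    return groups


def _chaid_candidate(
    cats: np.ndarray, y: np.ndarray, n_categories: int, params: InductionParams
) -> tuple[float, list[list[int]]] | None:
    """Best merged categorization of one binned attribute at a node.

    Returns (Bonferroni-adjusted p, groups of original bin indices) or None
    if no valid >= 2-way split exists. The Bonferroni multiplier is the
    number of ways to partition the c observed ordered categories into r
    contiguous non-empty groups: C(c-1, r-1).
    """
    observed = sorted(set(int(c) for c in cats))
    if len(observed) < 2:
        return None
    cat_counts = np.zeros((n_categories, 2), dtype=float)
    for c, label in zip(cats, y):
        cat_counts[int(c), int(label == CLASS_POS)] += 1
    groups = [[c] for c in observed]
    groups = _merge_adjacent(groups, cat_counts, params.alpha_merge)
    groups = _enforce_min_child(groups, cat_counts, params.min_child)
    if len(groups) < 2:
        return None
    table = np.vstack([cat_counts[g].sum(axis=0) for g in groups])
    _, p = chi_square_split_pvalue(table)
    c, r = len(observed), len(groups)
    bonferroni = math.comb(c - 1, r - 1)
    return min(1.0, p * bonferroni), groups


def _grow_chaid(
    X: pd.DataFrame,
    y: np.ndarray,
    params: InductionParams,
    depth: int,
) -> TreeNode:
    counts = _counts(y)
    node = TreeNode(n_instances=len(y), class_counts=counts,
                    leaf_class=_majority_class(counts))
    if depth >= params.max_depth or len(y) < params.min_parent or min(counts) == 0:
        return node
    # continuous attributes are quantile-binned from the rows at THIS node
    # (adaptive resolution; deep nodes see fine-grained local boundaries)
    best_attr: str | None = None
    best: tuple[float, list[list[int]]] | None = None
    best_edges: np.ndarray | None = None
    best_cats: np.ndarray | None = None
    for attr in sorted(X.columns):
        values = X[attr].to_numpy(dtype=float)
        edges = quantile_bin_edges(values, params.n_bins)
        cats = np.searchsorted(edges, values, side="left")
        cand = _chaid_candidate(cats, y, len(edges) + 1, params)
        if cand is None:
            continue
        if best is None or cand[0] < best[0] - 1e-15:
            best_attr, best, best_edges, best_cats = attr, cand, edges, cats
    if best is None or best[0] > params.alpha_split:
        return node
    adj_p, groups = best
    assert best_edges is not None and best_cats is not None
    # boundary between consecutive groups = lower edge of the next group's
    # first observed bin, so the intervals stay contiguous even when an
    # interior bin is empty at this node
    boundaries = [float(best_edges[min(g) - 1]) for g in groups[1:]]
    intervals = list(
        zip([-math.inf] + boundaries, boundaries + [math.inf])
    )
    child_nodes: list[TreeNode] = []
    for group in groups:
        mask = np.isin(best_cats, group)
        child_nodes.append(_grow_chaid(X.loc[mask], y[mask], params, depth + 1))
    node.split_attr = best_attr
    node.split_spec = {"kind": "intervals", "intervals": intervals, "adjusted_p": adj_p}
    node.leaf_class = None
    node.children = child_nodes
    return node


def induce_chaid(X: pd.DataFrame, y: np.ndarray, params: InductionParams) -> DecisionTreeModel:
    """Grow a CHAID tree: quantile-bin, merge, chi-square-select, split."""
    if params.paradigm != "CHAID":
        raise ValueError("params.paradigm must be CHAID")
    X, y, _dropped = _drop_missing(X, np.asarray(y))
    if len(y) == 0:
        raise ValueError("no complete rows to train on")
    root = _grow_chaid(X, y, params, depth=0)
    _attach_intervals_ok(root)
    return DecisionTreeModel(root=root, params=params, attributes=tuple(sorted(X.columns)))


def _attach_intervals_ok(node: TreeNode) -> None:
    """Sanity: CHAID interval children are ordered and contiguous."""
    if node.is_leaf or node.split_spec is None:
        return
    if node.split_spec.get("kind") == "intervals":
        ivs = node.split_spec["intervals"]
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            assert b == c, "CHAID intervals must be contiguous"
    for child in node.children:
        _attach_intervals_ok(child)


def induce(X: pd.DataFrame, y: np.ndarray, params: InductionParams) -> DecisionTreeModel:
    """Dispatch to the paradigm named in ``params``."""
    if params.paradigm == "CHAID":
        return induce_chaid(X, y, params)
    return induce_cart(X, y, params)


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------

def _route(node: TreeNode, row: Mapping[str, float]) -> TreeNode:
    while not node.is_leaf:
        attr = node.split_attr
        if attr not in row or row[attr] is None or (
            isinstance(row[attr], float) and math.isnan(row[attr])
        ):
            raise KeyError(f"missing attribute value for {attr!r}")
        value = float(row[attr])
        spec = node.split_spec or {}
        if spec.get("kind") == "threshold":
            op = spec.get("op", "<")
            if op == "<":
                match = value < spec["threshold"]
            elif op == ">":
                match = value > spec["threshold"]
            else:
                raise ValueError(f"unknown threshold op {op!r}")
            node = node.children[0] if match else node.children[1]
        elif spec.get("kind") == "intervals":
            intervals = spec["intervals"]
            chosen = len(intervals) - 1
            for i, (lo, hi) in enumerate(intervals):
                if value <= hi:
                    chosen = i
                    break
            node = node.children[chosen]
        else:
            raise ValueError("internal node without a split spec")
    return node


def predict_class(model: DecisionTreeModel, row: Mapping[str, float]) -> int:
    """Route one descriptor row from root to leaf; returns 0 (CNSp-) or 1 (CNSp+)."""
    leaf = _route(model.root, row)
    if leaf.unspecified or leaf.leaf_class is None:
        raise PublishedRuleUndefined(
            "routing reached a branch with no published threshold"
        )
    return leaf.leaf_class


def predict_frame(model: DecisionTreeModel, X: pd.DataFrame) -> np.ndarray:
    """Vector of class predictions for every row of ``X``."""
    return np.array([predict_class(model, row) for _, row in X.iterrows()], dtype=int)


# --------------------------------------------------------------------------
# Published decision rules
# --------------------------------------------------------------------------

def published_rule_classifier(paradigm: str) -> DecisionTreeModel:
    """Partial trees hard-coding every threshold printed in the source text.

    CHAID: aLogP < -1.0028 classifies CNSp- outright; otherwise fewer than
    four H-bond acceptors favours CNSp+ (rotatable-bond and fPSA3 nodes exist
    in the published figure but their thresholds are unprinted, so that
    branch is an explicit unspecified leaf).

    CART: in the low-aLogP branch, a Burden-matrix BCUTS above 11.9 gives
    CNSp-; in the high-aLogP branch, tPSA below 150 A^2 gives CNSp+ and
    150 or above gives CNSp- (high polarity blocks permeation). The text
    prints no CART aLogP cutoff, so the one printed aLogP threshold is used
    as the low/high boundary.
    """
    paradigm = paradigm.upper()
    unspec = TreeNode(n_instances=0, class_counts=(0, 0), unspecified=True)
    if paradigm == "CHAID":
        hba_node = TreeNode(
            n_instances=0,
            class_counts=(0, 0),
            split_attr="hBondAcceptors",
            split_spec={"kind": "threshold", "threshold": 4.0, "op": "<"},
            children=[
                TreeNode(n_instances=0, class_counts=(0, 0), leaf_class=CLASS_POS),
                unspec,
            ],
        )
        root = TreeNode(
            n_instances=0,
            class_counts=(0, 0),
            split_attr="aLogP",
            split_spec={"kind": "threshold", "threshold": -1.0028, "op": "<"},
            children=[
                TreeNode(n_instances=0, class_counts=(0, 0), leaf_class=CLASS_NEG),
                hba_node,
            ],
        )
        params = InductionParams(paradigm="CHAID")
        attrs = ("aLogP", "hBondAcceptors")
    elif paradigm == "CART":
        bcut_node = TreeNode(
            n_instances=0,
            class_counts=(0, 0),
            split_attr="BCUTS",
            split_spec={"kind": "threshold", "threshold": 11.9, "op": ">"},
            children=[
                TreeNode(n_instances=0, class_counts=(0, 0), leaf_class=CLASS_NEG),
                unspec,
            ],
        )
        tpsa_node = TreeNode(
            n_instances=0,
            class_counts=(0, 0),
            split_attr="tPSA",
            split_spec={"kind": "threshold", "threshold": 150.0, "op": "<"},
            children=[
                TreeNode(n_instances=0, class_counts=(0, 0), leaf_class=CLASS_POS),
                TreeNode(n_instances=0, class_counts=(0, 0), leaf_class=CLASS_NEG),
            ],
        )
        root = TreeNode(
            n_instances=0,
            class_counts=(0, 0),
            split_attr="aLogP",
            split_spec={"kind": "threshold", "threshold": -1.0028, "op": "<"},
            children=[bcut_node, tpsa_node],
        )
        params = InductionParams(paradigm="CART")
        attrs = ("BCUTS", "aLogP", "tPSA")
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    return DecisionTreeModel(root=root, params=params, attributes=attrs)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    d: dict[str, Any] = {
        "n_instances": node.n_instances,
        "class_counts": list(node.class_counts),
    }
    if node.unspecified:
        d["unspecified"] = True
    if node.is_leaf:
        if node.leaf_class is not None:
            d["leaf_class"] = CLASS_NAMES[node.leaf_class]
    else:
        d["split_attr"] = node.split_attr
        spec = dict(node.split_spec or {})
        if spec.get("kind") == "intervals":
            spec["intervals"] = [
                ["-inf" if math.isinf(lo) and lo < 0 else lo,
                 "inf" if math.isinf(hi) and hi > 0 else hi]
                for lo, hi in spec["intervals"]
            ]
        d["split_spec"] = spec
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    counts = tuple(d["class_counts"])
    node = TreeNode(
        n_instances=int(d["n_instances"]),
        class_counts=(int(counts[0]), int(counts[1])),
        unspecified=bool(d.get("unspecified", False)),
    )
    if "children" in d:
        spec = dict(d["split_spec"])
        if spec.get("kind") == "intervals":
            spec["intervals"] = [
                (
                    -math.inf if lo == "-inf" else float(lo),
                    math.inf if hi == "inf" else float(hi),
                )
                for lo, hi in spec["intervals"]
            ]
        node.split_attr = d["split_attr"]
        node.split_spec = spec
        node.children = [_node_from_dict(c) for c in d["children"]]
        child_sum = sum(c.n_instances for c in node.children)
        if child_sum != node.n_instances:
            raise ValueError(
                f"children n_instances sum to {child_sum}, parent has {node.n_instances}"
            )
        if len(node.children) < 2:
            raise ValueError("internal nodes must have >= 2 children")
    else:
        name_to_class = {v: k for k, v in CLASS_NAMES.items()}
        if "leaf_class" in d:
            node.leaf_class = name_to_class[d["leaf_class"]]
        elif not node.unspecified:
            raise ValueError("leaf without a class")
    return node


def serialize_tree(model: DecisionTreeModel) -> str:
    """Human-readable JSON tree document; round-trips byte-identically."""
    doc = {
        "paradigm": model.params.paradigm,
        "params": {
            "max_depth": model.params.max_depth,
            "min_parent": model.params.min_parent,
            "min_child": model.params.min_child,
            "alpha_split": model.params.alpha_split,
            "alpha_merge": model.params.alpha_merge,
            "n_bins": model.params.n_bins,
            "seed": model.params.seed,
        },
        "attributes": list(model.attributes),
        "root": _node_to_dict(model.root),
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def deserialize_tree(doc: str) -> DecisionTreeModel:
    """Parse a tree document, enforcing the structural invariants."""
    try:
        d = json.loads(doc)
        params = InductionParams(paradigm=d["paradigm"], **d["params"])
        root = _node_from_dict(d["root"])
        return DecisionTreeModel(root=root, params=params, attributes=tuple(d["attributes"]))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed tree document: {exc}") from exc


def to_dot(model: DecisionTreeModel) -> str:
    """Graphviz DOT rendering of the tree (for figures)."""
    lines = ["digraph tree {", "  node [shape=box];"]
    counter = [0]

    def visit(node: TreeNode) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if node.is_leaf:
            label = "unspecified" if node.unspecified else CLASS_NAMES[node.leaf_class]
            label += f"\\nn={node.n_instances}"
        else:
            label = f"{node.split_attr}\\nn={node.n_instances}"
        lines.append(f'  {name} [label="{label}"];')
        for i, child in enumerate(node.children):
            child_name = visit(child)
            spec = node.split_spec or {}
            if spec.get("kind") == "threshold":
                edge = f'{spec["op"]} {spec["threshold"]:g}' if i == 0 else "else"
            else:
                lo, hi = spec["intervals"][i]
                edge = f"({lo:g}, {hi:g}]"
            lines.append(f'  {name} -> {child_name} [label="{edge}"];')
        return name

    visit(model.root)
    lines.append("}")
    return "\n".join(lines)
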