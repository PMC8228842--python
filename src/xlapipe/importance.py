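"""Random-forest attribute importance by mean decrease in Gini.

Each forest tree is grown on a bootstrap resample with ``mtry`` candidate
attributes sampled per split.  An attribute's importance is the sum, over
the splits that use it, of the node-weighted Gini decrease
``(n_node/n_root) * (i_parent - w_left*i_left - w_right*i_right)``, averaged
over trees.  The exact importance values of the original study depend on
its unpublished patient data (and on R's random number stream), so only the
rank-order structure of the published table — laboratory measurements far
outranking family history and past-disease counts — is reproducible, and
that is what the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trees import (
    DecisionTree,
    Leaf,
    SplitControl,
    gini_impurity,
    grow_tree,
    predict,
    resolve_class_order,
)

#: Deep, unpruned trees: forests rely on averaging, not on per-tree control.
_FOREST_CONTROL = SplitControl(minsplit=2, maxdepth=25)


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    mtry: int | None = None  # default floor(sqrt(p))
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class Forest:
    trees: list[DecisionTree]
    oob_indices: list[np.ndarray]
    attributes: tuple[str, ...]
    target: str
    class_order: tuple[str, ...]
    config: ForestConfig


def build_forest(
    table: pd.DataFrame,
    target: str,
    attributes: Sequence[str],
    config: ForestConfig | None = None,
) -> Forest:
    """Grow a seeded, reproducible forest of CART trees."""
    config = config or ForestConfig()
    if table.empty:
        raise ValueError("training table is empty")
    attrs = tuple(attributes)
    p = len(attrs)
    mtry = config.mtry if config.mtry is not None else max(1, int(np.floor(np.sqrt(p))))
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds the {p} available attributes")
    rng = np.random.default_rng(config.seed)
    class_order = resolve_class_order(table[target].tolist())
    n = len(table)
    table = table.reset_index(drop=True)

    trees: list[DecisionTree] = []
    oob: list[np.ndarray] = []
    for _ in range(config.n_trees):
        if config.bootstrap:
            sample = rng.integers(0, n, size=n)
            out_of_bag = np.setdiff1d(np.arange(n), sample)
        else:
            sample = np.arange(n)
            out_of_bag = np.array([], dtype=int)
        tree = grow_tree(
            table.iloc[sample],
            target,
            attrs,
            _FOREST_CONTROL,
            class_order=class_order,
            _mtry=mtry if mtry < p else None,
            _rng=rng,
        )
        trees.append(tree)
        oob.append(out_of_bag)
    return Forest(trees, oob, attrs, target, class_order, config)


def _tree_importance(tree: DecisionTree) -> dict[str, float]:
    scores: dict[str, float] = {}
    root_n = sum(tree.root.class_counts.values())

    def walk(node) -> None:
        if isinstance(node, Leaf):
            return
        n = sum(node.class_counts.values())
        nl = sum(node.left.class_counts.values())
        nr = sum(node.right.class_counts.values())
        decrease = gini_impurity(node.class_counts) - (
            nl / n
        ) * gini_impurity(node.left.class_counts) - (nr / n) * gini_impurity(
            node.right.class_counts
        )
        scores[node.attribute] = scores.get(node.attribute, 0.0) + (n / root_n) * decrease
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    return scores


def gini_importance(forest: Forest) -> pd.Series:
    """Mean decrease in Gini per attribute, averaged over the forest's trees.

    Attributes never used by any split score exactly 0.
    """
    if not forest.trees:
        raise ValueError("forest has no trees")
    totals = {a: 0.0 for a in forest.attributes}
    for tree in forest.trees:
        for attr, score in _tree_importance(tree).items():
            totals[attr] += score
    n = len(forest.trees)
    return pd.Series({a: totals[a] / n for a in forest.attributes}, name="mean_decrease_gini")


def oob_accuracy(forest: Forest, table: pd.DataFrame, target: str) -> float:
    """Out-of-bag majority-vote accuracy (rows never out of bag are skipped)."""
    table = table.reset_index(drop=True)
    votes: dict[int, dict[str, int]] = {}
    records = table.to_dict(orient="records")
    for tree, oob in zip(forest.trees, forest.oob_indices):
        for i in oob:
            label = predict(tree, records[i])
            votes.setdefault(int(i), {})[label] = votes.setdefault(int(i), {}).get(label, 0) + 1
    if not votes:
        raise ValueError("no out-of-bag rows; was bootstrap disabled?")
    order = {lab: k for k, lab in enumerate(forest.class_order)}
    correct = 0
    for i, counts in votes.items():
        winner = max(counts, key=lambda lab: (counts[lab], -order.get(lab, 0)))
        correct += winner == table.loc[i, target]
    return correct / len(votes)


def importance_report(
    table: pd.DataFrame,
    attributes: Sequence[str] | dict[str, Sequence[str]],
    targets: Sequence[str],
    config: ForestConfig | None = None,
) -> pd.DataFrame:
    """Importance table shaped like the published ranking: one row per
    attribute, one mean-decrease-Gini column per target.

    ``attributes`` may be one shared list or a per-target mapping (needed
    when an attribute encodes one of the targets and must be excluded from
    its own forest).
    """
    config = config or ForestConfig()
    columns = {}
    for k, target in enumerate(targets):
        attrs = attributes[target] if isinstance(attributes, dict) else attributes
        attrs = [a for a in attrs if a != target]
        cfg = ForestConfig(config.n_trees, config.mtry, config.seed + k, config.bootstrap)
        forest = build_forest(table, target, attrs, cfg)
        columns[f"gini_{target}"] = gini_importance(forest)
    return pd.DataFrame(columns)
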