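"""CART-style classification trees with Gini impurity.

Binary threshold trees grown by exhaustive greedy search, controlled by
``minsplit`` (minimum node size eligible for splitting) and ``maxdepth``
(root at depth 0).  The split convention is fixed throughout the package:
``attribute < threshold`` goes left, ``>= threshold`` goes right, candidate
thresholds are midpoints between consecutive distinct sorted values, and
ties are broken by attribute order, then by the lower threshold.  Leaf
labels are majority class; label ties resolve by severity order
(very severe, severe, less severe) or, for unknown label sets, by order of
first appearance in the training column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd

#: Canonical severity order used for deterministic tie-breaking.  The
#: two-class mutation labels are a suffix of the three-class course labels,
#: so one ordering serves both targets.
SEVERITY_ORDER: tuple[str, ...] = ("very severe", "severe", "less severe")

_GAIN_TOL = 1e-12


@dataclass
class SplitControl:
    """Growth limits: ``minsplit`` observations to split, ``maxdepth`` levels."""

    minsplit: int = 8
    maxdepth: int = 5

    def __post_init__(self) -> None:
        if self.minsplit < 2:
            raise ValueError(f"minsplit must be >= 2, got {self.minsplit}")
        if self.maxdepth < 1:
            raise ValueError(f"maxdepth must be >= 1, got {self.maxdepth}")


@dataclass
class Leaf:
    label: str
    class_counts: dict[str, int]


@dataclass
class Internal:
    attribute: str
    threshold: float
    left: "Node"
    right: "Node"
    class_counts: dict[str, int]


Node = Union[Leaf, Internal]


@dataclass
class DecisionTree:
    """A fitted binary classification tree."""

    root: Node
    target: str
    class_order: tuple[str, ...]
    attributes: tuple[str, ...]
    control: SplitControl | None = None

    # -- structure ---------------------------------------------------------
    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def walk(node: Node) -> None:
            if isinstance(node, Leaf):
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    def depth(self) -> int:
        def d(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def paths(self) -> Iterator[tuple[list[tuple[str, float, bool]], Leaf]]:
        """Yield (path, leaf) pairs, left leaf first.

        Each path element is ``(attribute, threshold, went_left)``;
        ``went_left`` means the branch satisfied ``attribute < threshold``.
        """

        def walk(node: Node, path: list[tuple[str, float, bool]]):
            if isinstance(node, Leaf):
                yield path, node
            else:
                yield from walk(node.left, path + [(node.attribute, node.threshold, True)])
                yield from walk(node.right, path + [(node.attribute, node.threshold, False)])

        yield from walk(self.root, [])

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node: Node) -> dict:
            if isinstance(node, Leaf):
                return {"leaf": True, "label": node.label, "class_counts": node.class_counts}
            return {
                "leaf": False,
                "attribute": node.attribute,
                "threshold": node.threshold,
                "class_counts": node.class_counts,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "target": self.target,
            "class_order": list(self.class_order),
            "attributes": list(self.attributes),
            "root": enc(self.root),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DecisionTree":
        def dec(node: dict) -> Node:
            if node["leaf"]:
                return Leaf(node["label"], dict(node["class_counts"]))
            return Internal(
                node["attribute"],
                float(node["threshold"]),
                dec(node["left"]),
                dec(node["right"]),
                dict(node["class_counts"]),
            )

        return cls(
            root=dec(data["root"]),
            target=data["target"],
            class_order=tuple(data["class_order"]),
            attributes=tuple(data["attributes"]),
        )

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: Node, indent: int) -> None:
            pad = "  " * indent
            if isinstance(node, Leaf):
                lines.append(f"{pad}-> {node.label}  {node.class_counts}")
            else:
                lines.append(f"{pad}{node.attribute} < {node.threshold:g}?")
                walk(node.left, indent + 1)
                lines.append(f"{pad}{node.attribute} >= {node.threshold:g}?")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


@dataclass
class Partition:
    """Disjoint stratified train/test row-index sets."""

    train: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int


# ---------------------------------------------------------------------------
# impurity and split search
# ---------------------------------------------------------------------------

def gini_impurity(class_counts: Mapping[str, int]) -> float:
    """Gini impurity 1 - sum_k p_k^2 of a class-count map."""
    counts = np.asarray([c for c in class_counts.values()], dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def _gini_from_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise Gini for an (m, K) count matrix; rows with total 0 -> 0."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
    return 1.0 - np.sum(p * p, axis=1)


def _best_split_arrays(
    X: np.ndarray, y: np.ndarray, n_classes: int, attr_indices: Sequence[int]
) -> tuple[int, float, float] | None:
    """Best (attribute index, threshold, gain) over the given columns.

    Returns None when no candidate split has strictly positive gain.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    parent_imp = 1.0 - np.sum((parent_counts / n) ** 2)

    best: tuple[int, float, float] | None = None
    onehot = np.zeros((n, n_classes))
    for j in attr_indices:
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        boundaries = np.nonzero(xs[:-1] < xs[1:])[0]
        if boundaries.size == 0:
            continue
        onehot[:] = 0.0
        onehot[np.arange(n), y[order]] = 1.0
        cum = np.cumsum(onehot, axis=0)
        left_counts = cum[boundaries]
        right_counts = parent_counts - left_counts
        n_left = boundaries + 1.0
        n_right = n - n_left
        child = (n_left / n) * _gini_from_matrix(left_counts) + (
            n_right / n
        ) * _gini_from_matrix(right_counts)
        gains = parent_imp - child
        k = int(np.argmax(gains))
        # prefer the lowest threshold among (numerically) tied maxima
        tied = np.nonzero(gains >= gains[k] - _GAIN_TOL)[0]
        k = int(tied[0])
        gain = float(gains[k])
        if gain <= _GAIN_TOL:
            continue
        threshold = float((xs[boundaries[k]] + xs[boundaries[k] + 1]) / 2.0)
        if best is None or gain > best[2] + _GAIN_TOL:
            best = (j, threshold, gain)
    return best


def resolve_class_order(labels: Sequence[str]) -> tuple[str, ...]:
    """Deterministic class order: severity order when applicable, else
    order of first appearance."""
    uniq: list[str] = []
    for lab in labels:
        if lab not in uniq:
            uniq.append(lab)
    if set(uniq) <= set(SEVERITY_ORDER):
        return tuple(l for l in SEVERITY_ORDER if l in uniq)
    return tuple(uniq)


def _prepare(
    table: pd.DataFrame, target: str, attributes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    missing = [a for a in attributes if a not in table.columns]
    if missing:
        raise ValueError(f"attributes not in table: {missing}")
    X = table[list(attributes)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [a for a in attributes if table[a].isna().any()]
        raise ValueError(f"attributes contain missing values: {bad} (impute first)")
    class_order = resolve_class_order(table[target].tolist())
    codes = {lab: i for i, lab in enumerate(class_order)}
    y = table[target].map(codes).to_numpy(dtype=int)
    return X, y, class_order


def best_split(
    table: pd.DataFrame,
    target: str,
    attributes: Sequence[str],
    control: SplitControl | None = None,
) -> tuple[str, float, float] | None:
    """Best (attribute, threshold, gain) over all attributes and midpoints.

    The gain is the weighted decrease in Gini impurity.  Returns None when no
    split improves on the parent (including a pure node).
    """
    if not list(attributes):
        raise ValueError("attribute list is empty")
    control = control or SplitControl()
    if len(table) < control.minsplit:
        raise ValueError(
            f"node has {len(table)} rows, fewer than minsplit={control.minsplit}"
        )
    X, y, class_order = _prepare(table, target, attributes)
    hit = _best_split_arrays(X, y, len(class_order), range(len(attributes)))
    if hit is None:
        return None
    j, threshold, gain = hit
    return (list(attributes)[j], threshold, gain)


def grow_tree(
    table: pd.DataFrame,
    target: str,
    attributes: Sequence[str],
    control: SplitControl | None = None,
    *,
    class_order: Sequence[str] | None = None,
    _mtry: int | None = None,
    _rng: np.random.Generator | None = None,
) -> DecisionTree:
    """Grow a classification tree by recursive best-split search.

    Splitting stops at ``maxdepth``, below ``minsplit`` observations, on a
    pure node, or when no split has positive gain.  ``_mtry``/``_rng`` sample
    candidate attributes per node and exist for the random-forest builder.
    """
    if table.empty:
        raise ValueError("training table is empty")
    control = control or SplitControl()
    X, y, inferred_order = _prepare(table, target, attributes)
    order = tuple(class_order) if class_order is not None else inferred_order
    codes = {lab: i for i, lab in enumerate(order)}
    if class_order is not None:
        y = table[target].map(codes)
        if y.isna().any():
            raise ValueError("target contains labels outside class_order")
        y = y.to_numpy(dtype=int)
    n_classes = len(order)
    attrs = list(attributes)
    p = len(attrs)
    mtry = p if _mtry is None else _mtry

    def counts_of(idx: np.ndarray) -> dict[str, int]:
        bc = np.bincount(y[idx], minlength=n_classes)
        return {order[k]: int(bc[k]) for k in range(n_classes)}

    def majority(idx: np.ndarray) -> str:
        bc = np.bincount(y[idx], minlength=n_classes)
        # argmax takes the first maximum: class order breaks ties
        return order[int(np.argmax(bc))]

    def build(idx: np.ndarray, depth: int) -> Node:
        cc = counts_of(idx)
        pure = sum(1 for v in cc.values() if v > 0) <= 1
        if pure or depth >= control.maxdepth or len(idx) < control.minsplit:
            return Leaf(majority(idx), cc)
        if mtry < p:
            cand = sorted(_rng.choice(p, size=mtry, replace=False).tolist())
        else:
            cand = range(p)
        hit = _best_split_arrays(X[idx], y[idx], n_classes, cand)
        if hit is None:
            return Leaf(majority(idx), cc)
        j, threshold, _ = hit
        mask = X[idx, j] < threshold
        if not mask.any() or mask.all():  # degenerate midpoint rounding
            return Leaf(majority(idx), cc)
        return Internal(
            attrs[j],
            threshold,
            build(idx[mask], depth + 1),
            build(idx[~mask], depth + 1),
            cc,
        )

    root = build(np.arange(len(table)), 0)
    return DecisionTree(root, target, order, tuple(attrs), control)


# ---------------------------------------------------------------------------
# prediction, partitioning, evaluation
# ---------------------------------------------------------------------------

def predict(tree: DecisionTree, record: Mapping[str, float]) -> str:
    """Root-to-leaf descent; ``value < threshold`` goes left, ties go right."""
    node = tree.root
    while isinstance(node, Internal):
        try:
            value = record[node.attribute]
        except KeyError:
            raise KeyError(f"record is missing attribute {node.attribute!r}") from None
        node = node.left if value < node.threshold else node.right
    return node.label


def predict_table(tree: DecisionTree, table: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [predict(tree, row) for row in table.to_dict(orient="records")],
        index=table.index,
        name="prediction",
    )


def stratified_partition(
    table: pd.DataFrame, target: str, fraction: float, seed: int
) -> Partition:
    """Seeded stratified split; ``fraction`` is the training share.

    Per-class training counts follow largest-remainder rounding of
    ``fraction * n_class``, keeping every class within one observation of the
    global fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if table.empty:
        raise ValueError("cannot partition an empty table")
    rng = np.random.default_rng(seed)
    labels = table[target]
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for lab in resolve_class_order(labels.tolist()):
        idx = np.asarray(table.index[labels == lab])
        if idx.size == 0:
            raise ValueError(f"class {lab!r} has no rows")
        perm = rng.permutation(idx.size)
        quota = fraction * idx.size
        n_train = int(np.floor(quota))
        if quota - n_train >= 0.5:
            n_train += 1
        n_train = min(max(n_train, 0), idx.size)
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    return Partition(
        train=np.sort(np.concatenate(train_parts)),
        test=np.sort(np.concatenate(test_parts)),
        fraction=fraction,
        seed=seed,
    )


def accuracy(tree: DecisionTree, test_table: pd.DataFrame, target: str) -> float:
    """Fraction of rows whose prediction equals the target label."""
    if test_table.empty:
        raise ValueError("test table is empty")
    preds = predict_table(tree, test_table.drop(columns=[target]))
    return float((preds.to_numpy() == test_table[target].to_numpy()).mean())
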