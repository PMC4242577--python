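"""Categorical classification trees and linear discriminant analysis
over morphology tables.

The classification tree splits on categorical subset membership
(``value in subset`` vs not), greedily maximizing the decrease in Gini
impurity, with deterministic tie-breaking: first variable in column
order, then the lexicographically smallest qualifying subset.  The
discriminant analysis is classical Fisher LDA on (optionally
log10-transformed) continuous characters, reporting each function's
share of the between-group trace.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from cphylo.errors import ArgumentError

log = logging.getLogger(__name__)


# -- classification tree ----------------------------------------------


@dataclass
class TreeNode:
    """Internal split (variable, level subset) or leaf (majority class)."""

    majority: str
    counts: dict[str, int]
    variable: str | None = None
    subset: frozenset[str] | None = None
    left: "TreeNode | None" = None  # value in subset
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass
class FittedTree:
    root: TreeNode
    columns: list[str]

    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    def leaf_groups(self) -> list[dict[str, int]]:
        """Per-leaf class counts, left-to-right."""
        out: list[dict[str, int]] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(dict(node.counts))
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def predict_row(self, row: pd.Series) -> str:
        node = self.root
        while not node.is_leaf:
            # unseen levels fall through to the right (complement) branch
            node = node.left if row[node.variable] in node.subset else node.right
        return node.majority

    def predict(self, table: pd.DataFrame) -> pd.Series:
        return table.apply(self.predict_row, axis=1)


def _gini(labels: pd.Series) -> float:
    p = labels.value_counts(normalize=True).to_numpy()
    return 1.0 - float(np.sum(p**2))


def _candidate_subsets(levels: list[str]) -> list[frozenset[str]]:
    """Canonical binary partitions: nonempty proper subsets containing
    the lexicographically smallest level (each partition enumerated
    once), ordered smallest-first."""
    levels = sorted(levels)
    anchor, rest = levels[0], levels[1:]
    subsets = []
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            s = frozenset((anchor, *combo))
            if len(s) < len(levels):
                subsets.append(s)
    return sorted(subsets, key=lambda s: tuple(sorted(s)))


def fit_classification_tree(
    table: pd.DataFrame,
    labels: pd.Series,
    min_leaf: int = 5,
    min_split: int = 10,
    min_deviance_frac: float = 0.01,
) -> FittedTree:
    """Greedy binary classification tree on categorical characters.

    A split is accepted when both children have >= ``min_leaf`` rows
    and the weighted Gini decrease is at least ``min_deviance_frac`` of
    the root's weighted Gini.  Single-class input yields a one-leaf
    tree with a warning.
    """
    labels = pd.Series(labels).reset_index(drop=True).astype(str)
    table = table.reset_index(drop=True)
    if len(table) != len(labels):
        raise ArgumentError("table and labels differ in length")
    if labels.nunique() < 2:
        log.warning("single-class input; returning a trivial one-leaf tree")
    root_gini_total = _gini(labels) * len(labels)
    min_gain = min_deviance_frac * root_gini_total if root_gini_total > 0 else 0.0

    def build(idx: pd.Index) -> TreeNode:
        sub_labels = labels.loc[idx]
        counts = sub_labels.value_counts().to_dict()
        majority = sub_labels.value_counts().idxmax()
        node = TreeNode(majority=str(majority), counts={str(k): int(v) for k, v in counts.items()})
        if sub_labels.nunique() < 2 or len(idx) < min_split:
            return node
        parent_total = _gini(sub_labels) * len(idx)
        best = None  # (gain, col_pos, subset_key, subset, mask)
        for col_pos, col in enumerate(table.columns):
            values = table.loc[idx, col].astype(str)
            levels = values.unique().tolist()
            if len(levels) < 2:
                continue
            for subset in _candidate_subsets(levels):
                mask = values.isin(subset)
                n_l = int(mask.sum())
                n_r = len(idx) - n_l
                if n_l < min_leaf or n_r < min_leaf:
                    continue
                child_total = _gini(sub_labels[mask]) * n_l + _gini(sub_labels[~mask]) * n_r
                gain = parent_total - child_total
                key = (-gain, col_pos, tuple(sorted(subset)))
                if best is None or key < best[0]:
                    best = (key, col, subset, mask)
        if best is None or -best[0][0] < max(min_gain, 1e-12):
            return node
        _, col, subset, mask = best
        node.variable = col
        node.subset = subset
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return FittedTree(root=build(table.index), columns=list(table.columns))


def misclassification_rate(tree: FittedTree, table: pd.DataFrame, labels: pd.Series) -> float:
    """Fraction of rows whose leaf majority class differs from the label."""
    pred = tree.predict(table)
    return float(np.mean(pred.to_numpy() != pd.Series(labels).astype(str).to_numpy()))


# -- linear discriminant analysis -------------------------------------


@dataclass
class LDAModel:
    """Fisher discriminants over continuous characters.

    ``coefficients`` is (n_characters, n_functions); scores are
    ``(x - grand_mean) @ coefficients`` after applying the log10
    transform to ``log_columns``.  ``variance_fractions`` is each
    function's proportion of the between-group trace.
    """

    columns: list[str]
    log_columns: list[str]
    grand_mean: np.ndarray
    coefficients: np.ndarray
    variance_fractions: np.ndarray
    classes: list[str]
    class_means: np.ndarray = field(default=None)

    def coefficient_table(self) -> pd.DataFrame:
        names = [
            f"Log {c}" if c in self.log_columns else c for c in self.columns
        ]
        cols = [f"LD{i + 1}" for i in range(self.coefficients.shape[1])]
        return pd.DataFrame(self.coefficients, index=names, columns=cols)


def _apply_log(table: pd.DataFrame, log_columns: list[str]) -> pd.DataFrame:
    out = table.copy()
    for col in log_columns:
        x = out[col].to_numpy(dtype=float)
        nonpos = x <= 0
        if nonpos.any():
            floor = x[x > 0].min() if (x > 0).any() else 1e-6
            log.warning(
                "%d non-positive value(s) in log column %r clipped to %g",
                int(nonpos.sum()), col, floor,
            )
            x = np.where(nonpos, floor, x)
        out[col] = np.log10(x)
    return out


def lda_fit(
    table: pd.DataFrame,
    labels: pd.Series,
    log_columns: list[str] | None = None,
    ridge: float = 1e-8,
) -> LDAModel:
    """Fisher LDA: eigenvectors of within^-1 x between scatter.

    Coefficients are normalized so each function has unit pooled
    within-group variance (v' W v = 1 with W the pooled covariance)
    and signed so the largest-magnitude coefficient is positive.  A
    singular within-class scatter is regularized with a small ridge
    and a warning.
    """
    log_columns = list(log_columns or [])
    labels = pd.Series(labels).astype(str).reset_index(drop=True)
    table = table.reset_index(drop=True)
    unknown = set(log_columns) - set(table.columns)
    if unknown:
        raise ArgumentError(f"log columns not in table: {sorted(unknown)}")
    classes = sorted(labels.unique())
    k = len(classes)
    n, p = table.shape
    if n <= k:
        raise ArgumentError("need more rows than classes")
    X = _apply_log(table, log_columns).to_numpy(dtype=float)
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.empty((k, p))
    for ci, cls in enumerate(classes):
        sub = X[labels.to_numpy() == cls]
        mu = sub.mean(axis=0)
        means[ci] = mu
        centered = sub - mu
        Sw += centered.T @ centered
        Sb += len(sub) * np.outer(mu - grand, mu - grand)
    W = Sw / (n - k)  # pooled within-group covariance
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError:
        log.warning("singular within-class scatter; applying ridge %g", ridge)
        Sw = Sw + ridge * np.trace(Sw) / p * np.eye(p)
        W = Sw / (n - k)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_funcs = min(k - 1, p)
    evals = np.maximum(evals[order][:n_funcs], 0.0)
    vecs = evecs[:, order][:, :n_funcs]
    # unit pooled within-group variance per function
    for j in range(n_funcs):
        scale = float(vecs[:, j] @ W @ vecs[:, j])
        if scale > 0:
            vecs[:, j] = vecs[:, j] / np.sqrt(scale)
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return LDAModel(
        columns=list(table.columns),
        log_columns=log_columns,
        grand_mean=grand,
        coefficients=vecs,
        variance_fractions=fractions,
        classes=classes,
        class_means=means,
    )


def lda_project(model: LDAModel, table: pd.DataFrame) -> pd.DataFrame:
    """Discriminant scores for new rows (columns must match the fit)."""
    if list(table.columns) != model.columns:
        raise ArgumentError(
            f"column mismatch: expected {model.columns}, got {list(table.columns)}"
        )
    X = _apply_log(table.reset_index(drop=True), model.log_columns).to_numpy(dtype=float)
    scores = (X - model.grand_mean) @ model.coefficients
    return pd.DataFrame(scores, columns=[f"LD{i + 1}" for i in range(scores.shape[1])])
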