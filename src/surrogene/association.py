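"""Downstream association analyses on the surrogate state matrix.

Three uses of per-sample surrogate calls are implemented:

* **Drug sensitivity** — GI50 values are median-split into equal-sized
  sensitive / insensitive classes (equiprobable binning; by pharmacological
  convention LOW GI50 = sensitive), then a random-forest classifier is
  trained on binary surrogate/alteration features.  Features are ranked by
  mean Gini importance and the forest is refit on the top 10%; accuracy is
  reported as out-of-bag (OOB) error for both fits.
* **Molecular subtype** — per (gene, subtype) a one-vs-rest 2x2 Fisher
  exact test of significant-surrogate status against subtype membership.
* **Survival** — a k-group log-rank test, and a survival tree grown by
  greedy binary partitioning on binary surrogate features, choosing at each
  node the feature whose present/absent split maximizes the two-sample
  log-rank statistic, pruned by a chi-square complexity threshold and a
  leaf-count cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import fisher_exact
from sklearn.ensemble import RandomForestClassifier

from .core import SurrogateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "discretize_gi50",
    "fit_drug_classifier",
    "ClassifierReport",
    "subtype_association",
    "logrank_test",
    "SurvivalDataset",
    "SurvivalTree",
    "fit_survival_tree",
]


# ---------------------------------------------------------------------------
# drug sensitivity


def discretize_gi50(
    values: Sequence[float] | pd.Series, low_is_sensitive: bool = True
) -> pd.Series:
    """Equiprobable binning of GI50 values into sensitive (1) / insensitive (0).

    The non-missing values are median-split into two bins whose sizes differ
    by at most one; ties at the median are broken by stable input order, the
    earlier values going to the lower bin.  GI50 is the concentration needed
    to inhibit growth by 50%, so by default the LOW half is the sensitive
    class (*low_is_sensitive=False* flips the orientation).  Missing values
    propagate as missing.
    """
    s = pd.Series(values, dtype=float)
    mask = s.notna()
    n = int(mask.sum())
    if n < 4:
        raise ValueError(f"need >= 4 non-missing GI50 values, got {n}")
    order = np.argsort(s[mask].to_numpy(), kind="stable")
    n_low = n // 2  # lower bin is the smaller one when n is odd
    low_positions = order[:n_low]
    labels = pd.Series(np.nan, index=s.index, dtype=float)
    nonmissing_idx = s.index[mask]
    low_idx = nonmissing_idx[low_positions]
    labels[nonmissing_idx] = 0.0 if low_is_sensitive else 1.0
    labels[low_idx] = 1.0 if low_is_sensitive else 0.0
    return labels


@dataclass
class ClassifierReport:
    """Initial and importance-refined random-forest fit for one drug."""

    drug: str
    features_initial: list[str]
    features_refined: list[str]
    oob_error_initial: float
    oob_error_refined: float
    importances: dict[str, float]
    rng_seed: int


def _oob_error(forest: RandomForestClassifier) -> float:
    return float(1.0 - forest.oob_score_)


def fit_drug_classifier(
    features: pd.DataFrame,
    labels: Sequence[int] | pd.Series,
    rng_seed: int,
    refine_fraction: float = 0.10,
    n_estimators: int = 500,
    drug: str = "drug",
) -> ClassifierReport:
    """Random-forest sensitivity classifier with Gini-importance refinement.

    Fits a forest (*n_estimators* trees, sqrt(p) features per split) on the
    binary feature matrix, ranks features by mean Gini importance, refits on
    the top ``max(1, round(refine_fraction * p))`` features, and reports the
    out-of-bag error of both fits.  Deterministic given *rng_seed*.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    y = pd.Series(labels).to_numpy(dtype=float)
    if len(y) != len(features):
        raise ValueError("features and labels must be aligned (same length)")
    keep = ~np.isnan(y)  # samples without a GI50 label are dropped
    X = features.iloc[keep].reset_index(drop=True)
    y = y[keep].astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")

    def _fit(cols: list[str]) -> RandomForestClassifier:
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            oob_score=True,
            bootstrap=True,
            random_state=rng_seed,
            n_jobs=1,
        )
        rf.fit(X[cols].to_numpy(), y)
        return rf

    all_cols = list(features.columns)
    rf_full = _fit(all_cols)
    importances = dict(zip(all_cols, map(float, rf_full.feature_importances_)))
    n_keep = max(1, round(refine_fraction * len(all_cols)))
    ranked = sorted(all_cols, key=lambda c: (-importances[c], c))
    top = ranked[:n_keep]
    rf_top = _fit(top)
    return ClassifierReport(
        drug=drug,
        features_initial=all_cols,
        features_refined=top,
        oob_error_initial=_oob_error(rf_full),
        oob_error_refined=_oob_error(rf_top),
        importances=importances,
        rng_seed=rng_seed,
    )


def blend_probabilities(
    prob_a: np.ndarray, prob_b: np.ndarray, y: np.ndarray, weights: Sequence[float] | None = None
) -> pd.DataFrame:
    """Convex blend of two classifiers' positive-class probabilities.

    For each weight w on a grid, classifies by ``w * prob_a + (1-w) * prob_b
    >= 0.5`` and reports the error rate; a screening device for whether two
    feature sets combine profitably.
    """
    if weights is None:
        weights = np.linspace(0.0, 1.0, 11)
    rows = []
    for w in weights:
        blended = w * np.asarray(prob_a) + (1 - w) * np.asarray(prob_b)
        err = float(np.mean((blended >= 0.5).astype(int) != np.asarray(y)))
        rows.append((float(w), err))
    return pd.DataFrame(rows, columns=["weight_a", "error"])


# ---------------------------------------------------------------------------
# molecular subtype


def subtype_association(
    matrix: SurrogateMatrix, subtypes: Mapping[str, str]
) -> pd.DataFrame:
    """Fisher exact tests of surrogate status against molecular subtype.

    For every surrogate gene that is significant in at least one sample and
    every subtype label, builds the one-vs-rest 2x2 table {significant
    surrogate vs not} x {in subtype vs not} and reports the two-sided Fisher
    exact p-value with the direction of association.
    """
    labels = {s: subtypes[s] for s in matrix.samples if s in subtypes}
    uniq = sorted(set(labels.values()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct subtype labels")
    sig = matrix.significant().loc[list(labels)]
    rows = []
    for gene in matrix.genes:
        col = sig[gene]
        if col.sum() == 0:
            continue  # never significant anywhere: no contrast to test
        for subtype in uniq:
            in_sub = pd.Series([labels[s] == subtype for s in col.index], index=col.index)
            a = int(((col == 1) & in_sub).sum())
            b = int(((col == 1) & ~in_sub).sum())
            c = int(((col == 0) & in_sub).sum())
            d = int(((col == 0) & ~in_sub).sum())
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            direction = "enriched" if (a * d) > (b * c) else ("depleted" if (a * d) < (b * c) else "none")
            rows.append((gene, subtype, float(p), direction))
    return pd.DataFrame(rows, columns=["gene", "subtype", "p_value", "odds_direction"])


# ---------------------------------------------------------------------------
# survival


def logrank_test(
    groups: Mapping[str, str] | Sequence[str],
    time: Sequence[float],
    event: Sequence[int],
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value).

    The statistic has k-1 degrees of freedom.  *groups* may be a per-sample
    mapping (aligned with the order of *time*/*event* keys) or a sequence of
    group labels aligned positionally.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if isinstance(groups, Mapping):
        glab = np.asarray([groups[s] for s in groups])
        if len(glab) != len(time):
            raise ValueError("groups mapping and time/event lengths differ")
    else:
        glab = np.asarray(list(groups))
    if len(set(glab.tolist())) < 2:
        raise ValueError("need >= 2 groups")
    if event.sum() < 1:
        raise ValueError("need >= 1 event")
    res = multivariate_logrank_test(time, glab, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalDataset:
    """Binary feature matrix plus right-censored survival outcomes."""

    features: pd.DataFrame  # samples x binary features (0/1)
    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        vals = self.features.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("features must be binary 0/1")
        if (np.asarray(self.time, dtype=float) < 0).any():
            raise ValueError("time must be nonnegative")


@dataclass
class TreeNode:
    """Internal node (split on feature presence) or leaf (group id)."""

    feature: str | None = None
    absent: "TreeNode | None" = None  # feature == 0 branch
    present: "TreeNode | None" = None  # feature == 1 branch
    group: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class SurvivalTree:
    """Greedy log-rank partitioning of samples by binary features."""

    root: TreeNode
    groups: dict[int, list[str]]  # leaf group id -> sample ids
    max_leaves: int
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    split_features: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.groups)

    def assign(self, features: pd.DataFrame) -> pd.Series:
        """Leaf group id for each row of a binary feature matrix."""
        out = {}
        for sid, row in features.iterrows():
            node = self.root
            while not node.is_leaf:
                node = node.present if row[node.feature] == 1 else node.absent
            out[sid] = node.group
        return pd.Series(out, name="group")

    def render(self) -> str:
        """Bracket-text rendering, e.g. ``(TP53-:g0, (EGFR-:g1, EGFR+:g2))``."""

        def rec(node: TreeNode, label: str) -> str:
            if node.is_leaf:
                return f"{label}g{node.group}[n={len(self.groups[node.group])}]"
            left = rec(node.absent, f"{node.feature}-:")
            right = rec(node.present, f"{node.feature}+:")
            return f"{label}({left}, {right})"

        return rec(self.root, "")


def _two_sample_logrank(time, event, split_mask) -> float:
    """Two-sample log-rank chi-square for a present/absent split (0 if degenerate)."""
    if split_mask.sum() == 0 or (~split_mask).sum() == 0:
        return 0.0
    if event.sum() == 0:
        return 0.0
    res = multivariate_logrank_test(time, split_mask.astype(int), event)
    stat = float(res.test_statistic)
    return stat if np.isfinite(stat) else 0.0


def fit_survival_tree(
    data: SurvivalDataset,
    max_leaves: int = 4,
    min_leaf: int = 10,
    split_threshold: float = 3.84,
) -> SurvivalTree:
    """Grow a survival tree by greedy best-first log-rank splitting.

    At each step, among all current leaves and all features, the
    present/absent split with the largest two-sample log-rank statistic is
    applied, provided the statistic reaches *split_threshold* (default 3.84,
    the chi-square(1) critical value at 0.05 — the complexity criterion) and
    both children hold at least *min_leaf* samples.  Growth stops when no
    admissible split remains or the tree reaches *max_leaves* terminal
    groups.  If the root itself admits no split, a single-leaf tree is
    returned with a warning.
    """
    if len(data.features) < 2 * min_leaf:
        raise ValueError(
            f"need >= {2 * min_leaf} samples for min_leaf={min_leaf}, got {len(data.features)}"
        )
    X = data.features
    time = np.asarray(data.time, dtype=float)
    event = np.asarray(data.event, dtype=int)
    sample_ids = list(X.index)

    def best_split(rows: np.ndarray) -> tuple[str | None, float]:
        best_feat, best_stat = None, 0.0
        for feat in X.columns:
            mask = X[feat].to_numpy()[rows] == 1
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            stat = _two_sample_logrank(time[rows], event[rows], mask)
            if stat > best_stat + 1e-12 or (
                stat > best_stat - 1e-12 and best_feat is not None and str(feat) < best_feat
            ):
                best_feat, best_stat = str(feat), stat
        if best_stat < split_threshold:
            return None, best_stat
        return best_feat, best_stat

    root = TreeNode()
    all_rows = np.arange(len(sample_ids))
    # frontier: (node, row indices, candidate split feature, statistic)
    feat0, stat0 = best_split(all_rows) if max_leaves > 1 else (None, 0.0)
    if feat0 is None:
        logger.warning("no admissible split at root; returning single-leaf tree")
        root.group = 0
        groups = {0: sample_ids}
        return SurvivalTree(root=root, groups=groups, max_leaves=max_leaves)

    frontier: list[tuple[TreeNode, np.ndarray, str | None, float]] = [
        (root, all_rows, feat0, stat0)
    ]
    leaves: list[tuple[TreeNode, np.ndarray]] = []
    split_features: list[str] = []
    n_leaves = 1
    while frontier and n_leaves < max_leaves:
        # best-first: split the frontier node with the largest statistic
        frontier.sort(key=lambda t: -t[3])
        node, rows, feat, stat = frontier.pop(0)
        if feat is None:
            leaves.append((node, rows))
            continue
        mask = X[feat].to_numpy()[rows] == 1
        node.feature = feat
        split_features.append(feat)
        node.absent, node.present = TreeNode(), TreeNode()
        n_leaves += 1
        for child, child_rows in ((node.absent, rows[~mask]), (node.present, rows[mask])):
            cfeat, cstat = best_split(child_rows)
            frontier.append((child, child_rows, cfeat, cstat))
    leaves.extend((node, rows) for node, rows, _f, _s in frontier)

    groups: dict[int, list[str]] = {}
    for gid, (node, rows) in enumerate(leaves):
        node.group = gid
        groups[gid] = [sample_ids[i] for i in rows]

    tree = SurvivalTree(
        root=root, groups=groups, max_leaves=max_leaves, split_features=split_features
    )
    if tree.n_leaves >= 2:
        glab = np.empty(len(sample_ids), dtype=int)
        for gid, (node, rows) in enumerate(leaves):
            glab[rows] = gid
        stat, p = logrank_test(glab.tolist(), time, event)
        tree.logrank_statistic, tree.logrank_p = stat, p
    return tree
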