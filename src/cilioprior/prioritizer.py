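"""Class-balanced random forest scoring with out-of-bag FDR selection.

The forest implements its own bagging around single CART learners so that
per-tree bags are observable: each tree trains on ``n_pos`` positives
drawn with replacement plus ``n_pos`` negatives drawn without replacement
from the negative pool. A training gene is scored only by trees whose bag
excluded it (out-of-bag); unlabelled genes are scored by every tree.

The per-gene FDR at a score threshold is the proportion of training
negatives among training genes at or above the threshold (optionally
reweighted by a prior ratio), monotonized so FDR never increases with
score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .labels import LabelSet
from .screen_stats import roc_auc

__all__ = [
    "ForestConfig",
    "BalancedRandomForest",
    "train_balanced_forest",
    "estimate_fdr",
    "select_candidates",
    "cross_replicate_protocol",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; ``mtry="sqrt"`` uses the square-root rule."""

    ntree: int = 5000
    mtry: int | str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class BalancedRandomForest:
    """Bagged CART ensemble with per-tree class balancing and OOB votes."""

    def __init__(self, config: ForestConfig):
        self.config = config
        self.trees_: list[DecisionTreeClassifier] = []
        self.inbag_: list[np.ndarray] = []
        self._n_train = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        if pos_idx.size < 2 or neg_idx.size < 2:
            raise ValueError("need at least 2 genes per class to train")
        if neg_idx.size < pos_idx.size:
            raise ValueError(
                "negative pool smaller than positive set; balanced "
                "undersampling undefined"
            )
        n_pos = pos_idx.size
        mtry = self.config.mtry
        if isinstance(mtry, int) and mtry > X.shape[1]:
            raise ValueError("mtry exceeds the feature count")
        rng = np.random.default_rng(
            np.random.SeedSequence([self.config.seed, X.shape[1]])
        )
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.config.ntree)
        self.trees_ = []
        self.inbag_ = []
        self._n_train = X.shape[0]
        for t in range(self.config.ntree):
            boot_pos = rng.choice(pos_idx, size=n_pos, replace=True)
            samp_neg = rng.choice(neg_idx, size=n_pos, replace=False)
            bag = np.concatenate([boot_pos, samp_neg])
            y_bag = np.concatenate(
                [np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)]
            )
            tree = DecisionTreeClassifier(
                max_features=mtry, random_state=int(tree_seeds[t])
            )
            tree.fit(X[bag], y_bag)
            self.trees_.append(tree)
            self.inbag_.append(bag)
        return self

    def bag_class_counts(self) -> list[tuple[int, int]]:
        """(positives, negatives) drawn into each tree's bag (instrumentation)."""
        counts = []
        n_pos = len(self.inbag_[0]) // 2
        for bag in self.inbag_:
            counts.append((n_pos, len(bag) - n_pos))
        return counts

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting positive, over all trees."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / len(self.trees_)

    def oob_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Out-of-bag vote fraction for the training rows.

        Returns ``(scores, tree_counts)``; rows never out-of-bag (only
        possible with very few trees) get the all-tree vote fraction and
        a count of 0.
        """
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        counts = np.zeros(X.shape[0])
        for tree, bag in zip(self.trees_, self.inbag_):
            oob = np.ones(X.shape[0], dtype=bool)
            oob[np.unique(bag)] = False
            if not oob.any():
                continue
            votes[oob] += tree.predict(X[oob])
            counts[oob] += 1
        scores = np.full(X.shape[0], np.nan)
        covered = counts > 0
        scores[covered] = votes[covered] / counts[covered]
        if (~covered).any():
            scores[~covered] = self.predict_scores(X[~covered])
        return scores, counts


def _training_split(
    genes: Sequence[str], labels: LabelSet
) -> tuple[np.ndarray, np.ndarray]:
    gene_arr = np.asarray(genes)
    is_pos = np.isin(gene_arr, list(labels.positives))
    is_neg = np.isin(gene_arr, list(labels.negatives))
    if is_pos.sum() == 0 or is_neg.sum() == 0:
        raise ValueError("a training class is absent from the feature matrix")
    return is_pos, is_neg


def _as_frame(features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return features.data if isinstance(features, FeatureMatrix) else features


def train_balanced_forest(
    features: FeatureMatrix | pd.DataFrame,
    labels: LabelSet,
    config: ForestConfig,
) -> pd.DataFrame:
    """Score every gene in the feature matrix.

    Training genes receive out-of-bag scores; all other genes the
    all-tree vote fraction. Returns a score table with columns ``gene``,
    ``score``, ``oob_trees``, ``fdr`` (unfilled), ``percentile`` and
    ``high_confidence`` (unset).
    """
    df = _as_frame(features)
    is_pos, is_neg = _training_split(df.index, labels)
    is_train = is_pos | is_neg
    X = df.to_numpy(dtype=float)
    y = np.where(is_pos[is_train], 1, 0)

    forest = BalancedRandomForest(config).fit(X[is_train], y)
    scores = np.empty(len(df))
    oob_counts = np.zeros(len(df))
    train_scores, train_counts = forest.oob_scores(X[is_train])
    scores[is_train] = train_scores
    oob_counts[is_train] = train_counts
    if (~is_train).any():
        scores[~is_train] = forest.predict_scores(X[~is_train])
        oob_counts[~is_train] = config.ntree

    percentile = scipy.stats.rankdata(scores, method="average") / len(scores) * 100
    return pd.DataFrame(
        {
            "gene": df.index,
            "score": scores,
            "oob_trees": oob_counts.astype(int),
            "fdr": np.nan,
            "percentile": percentile,
            "high_confidence": False,
        }
    ).reset_index(drop=True)


def estimate_fdr(
    score_table: pd.DataFrame,
    labels: LabelSet,
    *,
    neg_prior: float = 1.0,
) -> pd.DataFrame:
    """Fill the ``fdr`` column from scores and training labels.

    Raw FDR at threshold t = (training negatives scoring >= t) *
    ``neg_prior`` / (training genes scoring >= t); 0 by convention where no
    training gene reaches t. A step-down pass from the top score
    monotonizes the curve so FDR is non-increasing in score; each gene's
    FDR is the monotonized value at its own score.
    """
    table = score_table.copy()
    genes = table["gene"].to_numpy()
    scores = table["score"].to_numpy(dtype=float)
    is_pos = np.isin(genes, list(labels.positives))
    is_neg = np.isin(genes, list(labels.negatives))
    if not (is_pos.any() and is_neg.any()):
        raise ValueError("scores for both training classes are required")
    train_scores = scores[is_pos | is_neg]
    train_neg = scores[is_neg]

    thresholds = np.unique(scores)[::-1]  # descending
    fdr_at = {}
    running_max = 0.0
    for t in thresholds:
        n_train = int((train_scores >= t).sum())
        if n_train == 0:
            raw = 0.0
        else:
            raw = min(1.0, neg_prior * int((train_neg >= t).sum()) / n_train)
        running_max = max(running_max, raw)
        fdr_at[t] = running_max
    table["fdr"] = [fdr_at[s] for s in scores]
    return table


def select_candidates(
    score_table: pd.DataFrame, fdr_cutoff: float = 0.1
) -> tuple[list[str], pd.DataFrame]:
    """High-confidence genes: FDR strictly below the cutoff.

    Returns the selected genes sorted by descending score and the table
    with ``high_confidence`` flags set.
    """
    if score_table["fdr"].isna().any():
        raise ValueError("fdr column must be filled before selection")
    table = score_table.copy()
    table["high_confidence"] = table["fdr"] < fdr_cutoff
    selected = (
        table[table["high_confidence"]]
        .sort_values(["score", "gene"], ascending=[False, True])["gene"]
        .tolist()
    )
    return selected, table


def cross_replicate_protocol(
    features_rep1: pd.DataFrame,
    features_rep2: pd.DataFrame,
    labels: LabelSet,
    config: ForestConfig,
) -> dict[str, float]:
    """Train on one replicate, test on the other, both ways, plus a
    combined-feature out-of-bag AUC.

    Held-out AUCs are computed on the training genes of the tested
    replicate; the combined run concatenates both replicates' columns and
    evaluates out-of-bag.
    """
    if not features_rep1.index.equals(features_rep2.index):
        raise ValueError("replicates must share the same gene order")
    is_pos, is_neg = _training_split(features_rep1.index, labels)
    is_train = is_pos | is_neg
    y = np.where(is_pos[is_train], 1, 0)

    def held_out_auc(train_df: pd.DataFrame, test_df: pd.DataFrame) -> float:
        forest = BalancedRandomForest(config).fit(
            train_df.to_numpy(dtype=float)[is_train], y
        )
        preds = forest.predict_scores(test_df.to_numpy(dtype=float)[is_train])
        return roc_auc(preds, y)

    auc_12 = held_out_auc(features_rep1, features_rep2)
    auc_21 = held_out_auc(features_rep2, features_rep1)

    combined = pd.concat(
        [features_rep1.add_prefix("rep1_"), features_rep2.add_prefix("rep2_")],
        axis=1,
    )
    forest = BalancedRandomForest(config).fit(
        combined.to_numpy(dtype=float)[is_train], y
    )
    oob, _ = forest.oob_scores(combined.to_numpy(dtype=float)[is_train])
    auc_comb = roc_auc(oob, y)
    return {
        "auc_train1_test2": auc_12,
        "auc_train2_test1": auc_21,
        "auc_combined_oob": auc_comb,
    }
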