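"""Forest-based recursive feature elimination and subset-size grid search.

Ranking: classic RFE — fit a random forest, drop the ``step`` features with
the lowest impurity-decrease importance, refit, repeat; the final ranking is
the reverse elimination order (ties within a round broken by canonical
feature-name order so runs are deterministic).  A single-shot mode ranks by
one forest fit without re-fitting between eliminations.

Subset choice: evaluate prefixes of the ranking at sizes 50, 100, ... up to
all features by stratified cross-validated AUC with a fresh forest per size;
the chosen size is the argmax, ties broken toward the smaller subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .evaluation import pairwise_auc, stratified_folds


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered most-important-first with monotone importance scores.

    Scores combine the elimination round (later elimination = higher) with
    the within-round normalized forest importance, so they decrease along
    the ranking by construction while preserving each round's ordering.
    """

    ordered_features: tuple[str, ...]
    importance: tuple[float, ...]
    ranking_seed: int

    def __post_init__(self) -> None:
        if len(self.ordered_features) != len(self.importance):
            raise ValueError("ranking and importance lengths differ")


@dataclass(frozen=True)
class SelectedSubset:
    scheme: str
    features: tuple[str, ...]
    grid_scores: Mapping[int, float]
    chosen_size: int

    def __post_init__(self) -> None:
        if self.chosen_size != len(self.features):
            raise ValueError("chosen_size must equal len(features)")
        if self.chosen_size not in self.grid_scores:
            raise ValueError("chosen_size not in evaluated grid")


def _make_forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def _check_Xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if X.shape[0] != len(y):
        raise ValueError("X and y row counts differ")
    return y


def rfe_rank(
    X: pd.DataFrame,
    y: Sequence[int],
    step: int = 50,
    seed: int = 0,
    n_trees: int = 200,
    mode: str = "rfe",
    importance: str = "impurity",
) -> FeatureRanking:
    """Rank features by recursive elimination (or one-shot forest importance).

    mode="rfe" refits after each elimination round; mode="single" ranks from
    one fit.  importance="permutation" swaps impurity decrease for
    permutation importance on the training data.
    """
    y = _check_Xy(X, y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if step < 1:
        raise ValueError("step must be >= 1")
    remaining = list(X.columns)
    canon = {name: i for i, name in enumerate(X.columns)}
    batches: list[list[tuple[str, float]]] = []  # elimination order

    def _importances(cols: list[str]) -> np.ndarray:
        forest = _make_forest(n_trees, seed)
        forest.fit(X[cols].to_numpy(), y)
        if importance == "permutation":
            r = permutation_importance(
                forest, X[cols].to_numpy(), y, n_repeats=5, random_state=seed
            )
            return r.importances_mean
        return forest.feature_importances_

    if mode == "single":
        imp = _importances(remaining)
        order = sorted(
            range(len(remaining)), key=lambda i: (-imp[i], canon[remaining[i]])
        )
        mx = imp.max() if imp.max() > 0 else 1.0
        return FeatureRanking(
            ordered_features=tuple(remaining[i] for i in order),
            importance=tuple(float(imp[i] / mx) for i in order),
            ranking_seed=seed,
        )
    if mode != "rfe":
        raise ValueError(f"unknown mode {mode!r}")

    while remaining:
        imp = _importances(remaining)
        mx = imp.max() if imp.max() > 0 else 1.0
        ranked = sorted(
            zip(remaining, imp / mx),
            key=lambda t: (t[1], -canon[t[0]]),
        )  # least important first; name-order tie-break
        if len(remaining) <= step:
            batches.append(ranked)
            break
        drop = ranked[:step]
        batches.append(drop)
        dropped = {name for name, _ in drop}
        remaining = [f for f in remaining if f not in dropped]

    ordered: list[str] = []
    scores: list[float] = []
    # later rounds are more important; within a round, higher importance first
    for round_idx in range(len(batches) - 1, -1, -1):
        for name, norm_imp in reversed(batches[round_idx]):
            ordered.append(name)
            scores.append(round_idx + float(norm_imp))
    return FeatureRanking(
        ordered_features=tuple(ordered),
        importance=tuple(scores),
        ranking_seed=seed,
    )


def grid_sizes(n_features: int, grid_step: int) -> list[int]:
    sizes = list(range(grid_step, n_features, grid_step))
    sizes.append(n_features)
    return sizes


def grid_select(
    ranking: FeatureRanking,
    X: pd.DataFrame,
    y: Sequence[int],
    grid_step: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
    n_trees: int = 200,
    scheme: str = "",
) -> SelectedSubset:
    """Pick the prefix size with the best cross-validated AUC.

    Sizes run 50, 100, ... up to all features; ties go to the smaller size.
    """
    y = _check_Xy(X, y)
    if grid_step < 1 or cv_folds < 2:
        raise ValueError("grid_step >= 1 and cv_folds >= 2 required")
    sizes = grid_sizes(len(ranking.ordered_features), grid_step)
    folds = stratified_folds(y, cv_folds, seed)
    scores: dict[int, float] = {}
    for size in sizes:
        cols = list(ranking.ordered_features[:size])
        Xs = X[cols].to_numpy()
        aucs = []
        for train_idx, test_idx in folds:
            forest = _make_forest(n_trees, seed)
            forest.fit(Xs[train_idx], y[train_idx])
            probs = forest.predict_proba(Xs[test_idx])[:, 1]
            aucs.append(pairwise_auc(probs, y[test_idx]))
        scores[size] = float(np.mean(aucs))
    best = max(sorted(scores), key=lambda s: scores[s])  # ties -> smaller
    return SelectedSubset(
        scheme=scheme,
        features=tuple(ranking.ordered_features[:best]),
        grid_scores=scores,
        chosen_size=best,
    )


class RFESubsetSelector(BaseEstimator):
    """Ranking + grid selection as one sklearn-style estimator.

    Fitted attributes: ranking_, subset_, selected_features_.
    """

    def __init__(
        self,
        step: int = 50,
        grid_step: int = 50,
        cv_folds: int = 5,
        n_trees: int = 200,
        mode: str = "rfe",
        random_state: int = 0,
        scheme: str = "",
    ):
        self.step = step
        self.grid_step = grid_step
        self.cv_folds = cv_folds
        self.n_trees = n_trees
        self.mode = mode
        self.random_state = random_state
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "RFESubsetSelector":
        self.ranking_ = rfe_rank(
            X, y, step=self.step, seed=self.random_state,
            n_trees=self.n_trees, mode=self.mode,
        )
        self.subset_ = grid_select(
            self.ranking_, X, y, grid_step=self.grid_step,
            cv_folds=self.cv_folds, seed=self.random_state,
            n_trees=self.n_trees, scheme=self.scheme,
        )
        self.selected_features_ = list(self.subset_.features)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]


def ranking_to_frame(ranking: FeatureRanking) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.ordered_features) + 1),
            "feature_name": ranking.ordered_features,
            "importance": ranking.importance,
        }
    )


def grid_to_frame(subset: SelectedSubset) -> pd.DataFrame:
    sizes = sorted(subset.grid_scores)
    return pd.DataFrame(
        {"size": sizes, "mean_auc": [subset.grid_scores[s] for s in sizes]}
    )
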