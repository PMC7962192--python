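"""Per-encoding random forests fused into a single nitrotyrosine score.

One forest is trained per encoding scheme on its selected feature subset;
each produces a positive-class probability per window, and the final score
is a convex combination

    score_i = sum_s weight_s * prob_{s,i},  weight_s >= 0, sum_s weight_s = 1.

Weights are either fixed (the published operating point is 0.01 binary,
0.01 AAindex, 0.30 CKSAAP, 0.68 K-mer) or optimized by exhaustive search
over the simplex lattice against out-of-fold cross-validated AUC, so the
fusion never sees probabilities from the folds a forest was trained on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from . import __version__
from .encoders import (
    DEFAULT_PROPERTY_SET,
    EncodingSpec,
    SCHEMES,
    encode_dataset,
    load_default_properties,
)
from .evaluation import (
    evaluate_scores,
    pairwise_auc,
    stratified_folds,
    summarize_folds,
    threshold_at_specificity,
)
from .feature_selection import (
    FeatureRanking,
    SelectedSubset,
    grid_select,
    rfe_rank,
)
from .sequence_io import SiteWindow, labels_array

#: published fusion weights (binary, aaindex, cksaap, kmer)
PAPER_WEIGHTS = {"binary": 0.01, "aaindex": 0.01, "cksaap": 0.30, "kmer": 0.68}


class EnsembleError(ValueError):
    pass


class EnsembleLoadError(EnsembleError):
    pass


@dataclass(frozen=True)
class FusionWeights:
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(SCHEMES) - set(self.weights)
        if missing:
            raise EnsembleError(f"missing scheme weights {sorted(missing)}")
        vals = np.array([self.weights[s] for s in SCHEMES], dtype=float)
        if (vals < 0).any():
            raise EnsembleError("weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise EnsembleError(f"weights sum to {vals.sum()}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[s] for s in SCHEMES], dtype=float)


@dataclass
class TrainedEncodingModel:
    scheme: str
    subset: SelectedSubset
    forest: object  # fitted classifier (opaque handle)
    n_trees: int
    train_seed: int


@dataclass
class TrainedEnsemble:
    models: dict[str, TrainedEncodingModel]
    fusion: FusionWeights
    specs: dict[str, EncodingSpec]
    version: str = __version__

    def __post_init__(self) -> None:
        missing = set(SCHEMES) - set(self.models)
        if missing:
            raise EnsembleError(f"ensemble missing schemes {sorted(missing)}")


def stage_seed(base: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one top-level seed."""
    return int(
        np.random.SeedSequence(
            [int(base) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


def make_classifier(algorithm: str, n_trees: int, seed: int):
    """rf (the shipped predictor) plus nb/knn comparators."""
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=seed, n_jobs=1,
        )
    if algorithm == "nb":
        return GaussianNB()
    if algorithm == "knn":
        return None  # chosen per-fit by CV over k
    raise EnsembleError(f"unknown algorithm {algorithm!r}")


def _fit_knn(X: np.ndarray, y: np.ndarray, seed: int) -> KNeighborsClassifier:
    """k-NN with k picked from {3,5,7,9} by internal 3-fold AUC."""
    best_k, best_auc = 3, -1.0
    folds = stratified_folds(y, min(3, int(np.bincount(y).min())), seed)
    for k in (3, 5, 7, 9):
        if k >= len(y):
            continue
        aucs = []
        for tr, te in folds:
            knn = KNeighborsClassifier(n_neighbors=min(k, len(tr)))
            knn.fit(X[tr], y[tr])
            aucs.append(pairwise_auc(knn.predict_proba(X[te])[:, 1], y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_k, best_auc = k, mean_auc
    knn = KNeighborsClassifier(n_neighbors=best_k)
    knn.fit(X, y)
    return knn


def train_single(
    X: pd.DataFrame,
    y: Sequence[int],
    subset: SelectedSubset,
    n_trees: int = 500,
    seed: int = 0,
    algorithm: str = "rf",
) -> TrainedEncodingModel:
    """Fit one classifier on the subset columns of X."""
    missing = [f for f in subset.features if f not in X.columns]
    if missing:
        raise EnsembleError(f"subset features absent from matrix: {missing[:5]}")
    y = np.asarray(y, dtype=int)
    Xs = X[list(subset.features)].to_numpy()
    if algorithm == "knn":
        clf = _fit_knn(Xs, y, seed)
    else:
        clf = make_classifier(algorithm, n_trees, seed)
        clf.fit(Xs, y)
    return TrainedEncodingModel(
        scheme=subset.scheme, subset=subset, forest=clf,
        n_trees=n_trees, train_seed=seed,
    )


def predict_single(model: TrainedEncodingModel, X: pd.DataFrame) -> np.ndarray:
    missing = [f for f in model.subset.features if f not in X.columns]
    if missing:
        raise EnsembleError(f"matrix missing model features: {missing[:5]}")
    probs = model.forest.predict_proba(X[list(model.subset.features)].to_numpy())
    pos_col = list(model.forest.classes_).index(1)
    return probs[:, pos_col]


def fuse_scores(
    per_scheme_probs: Mapping[str, Sequence[float]], fusion: FusionWeights
) -> np.ndarray:
    lengths = {len(v) for v in per_scheme_probs.values()}
    if len(lengths) != 1:
        raise EnsembleError(f"probability lengths differ: {sorted(lengths)}")
    P = np.column_stack(
        [np.asarray(per_scheme_probs[s], dtype=float) for s in SCHEMES]
    )
    return P @ fusion.as_array()


def _lattice(m: int):
    for a in range(m + 1):
        for b in range(m + 1 - a):
            for c in range(m + 1 - a - b):
                yield a, b, c, m - a - b - c


def optimize_weights(
    per_scheme_probs: Mapping[str, Sequence[float]],
    y: Sequence[int],
    grid_step: float = 0.01,
    coarse_step: float = 0.05,
) -> FusionWeights:
    """Exhaustive simplex-lattice search maximizing AUC of the fused score.

    A coarse pass (default 0.05) is refined at grid_step (default 0.01)
    around the coarse optimum.  The probabilities must be out-of-fold.
    Ties prefer the weight vector with the largest single-scheme mass.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise EnsembleError("both classes required to optimize weights")
    P = np.column_stack(
        [np.asarray(per_scheme_probs[s], dtype=float) for s in SCHEMES]
    )

    def search(candidates) -> tuple[np.ndarray, float]:
        best_w, best_auc = None, -1.0
        for w in candidates:
            w = np.asarray(w, dtype=float)
            auc = pairwise_auc(P @ w, y)
            if auc > best_auc + 1e-12 or (
                abs(auc - best_auc) <= 1e-12
                and best_w is not None
                and (
                    w.max() > best_w.max() + 1e-12
                    or (abs(w.max() - best_w.max()) <= 1e-12
                        and tuple(w) > tuple(best_w))
                )
            ):
                best_w, best_auc = w, auc
            elif best_w is None:
                best_w, best_auc = w, auc
        return best_w, best_auc

    m = round(1 / coarse_step)
    coarse = [(a / m, b / m, c / m, d / m) for a, b, c, d in _lattice(m)]
    w0, _ = search(coarse)

    r = round(coarse_step / grid_step)  # refinement radius in fine units
    fine_m = round(1 / grid_step)
    base = np.round(w0 * fine_m).astype(int)
    fine = []
    for da in range(-r, r + 1):
        for db in range(-r, r + 1):
            for dc in range(-r, r + 1):
                dd = -(da + db + dc)
                if abs(dd) > r:
                    continue
                cand = base + np.array([da, db, dc, dd])
                if (cand >= 0).all() and cand.sum() == fine_m:
                    fine.append(tuple(cand / fine_m))
    w_best, _ = search(fine)
    return FusionWeights(dict(zip(SCHEMES, (float(v) for v in w_best))))


def ensemble_predict(
    ensemble: TrainedEnsemble, windows: Sequence[SiteWindow]
) -> pd.DataFrame:
    """Per-scheme and fused scores for a set of windows."""
    per_scheme: dict[str, np.ndarray] = {}
    tables = None
    for scheme in SCHEMES:
        spec = ensemble.specs[scheme]
        if scheme == "aaindex" and tables is None:
            tables = load_default_properties()
        X = encode_dataset(windows, spec, tables if scheme == "aaindex" else None)
        per_scheme[scheme] = predict_single(ensemble.models[scheme], X)
    fused = fuse_scores(per_scheme, ensemble.fusion)
    out = pd.DataFrame(
        {
            "protein_id": [sw.protein_id for sw in windows],
            "position": [sw.center_position for sw in windows],
            "window": [sw.residues for sw in windows],
            "score": fused,
        }
    )
    for scheme in SCHEMES:
        out[f"score_{scheme}"] = per_scheme[scheme]
    return out


def save_ensemble(ensemble: TrainedEnsemble, path: str | Path) -> None:
    joblib.dump(
        {"format": "prednts-ensemble", "version": ensemble.version,
         "ensemble": ensemble},
        path,
    )


def load_ensemble(path: str | Path, strict_version: bool = False) -> TrainedEnsemble:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted archive must not yield garbage
        raise EnsembleLoadError(f"cannot load ensemble from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "prednts-ensemble":
        raise EnsembleLoadError(f"{path} is not a prednts ensemble bundle")
    if strict_version and payload["version"] != __version__:
        raise EnsembleLoadError(
            f"bundle version {payload['version']} != library {__version__}"
        )
    ensemble = payload["ensemble"]
    missing = set(SCHEMES) - set(ensemble.models)
    if missing:
        raise EnsembleLoadError(f"bundle missing schemes {sorted(missing)}")
    return ensemble


class PredNTS(ClassifierMixin, BaseEstimator):
    """Nitrotyrosine site classifier over Y-centred sequence windows.

    fit() encodes the windows under all four schemes, optionally selects
    features per scheme (forest RFE + subset-size grid), trains one forest
    per scheme, computes out-of-fold probabilities for weight fusion, and
    stores the fused operating threshold.

    Parameters
    ----------
    w : half-window; windows are 2*w+1 residues (default 20 -> length 41).
    weights : "optimize" for the simplex-lattice search on out-of-fold
        probabilities, or a mapping scheme -> weight (e.g. PAPER_WEIGHTS).
    feature_selection : run per-scheme RFE + grid selection before training.
    rank_mode : "rfe" (classic re-fitting elimination) or "single"
        (one-shot forest ranking).
    threshold_mode : "fixed" uses ``threshold``; "specificity" calibrates
        the threshold so out-of-fold specificity reaches ``target_sp``.
    algorithm : "rf" (the shipped predictor); "nb"/"knn" comparators share
        the same interface for benchmarking.
    """

    def __init__(
        self,
        w: int = 20,
        k_values: tuple[int, ...] = (0, 1, 2, 3, 4),
        K_values: tuple[int, ...] = (1, 2, 3),
        property_set: tuple[str, ...] = DEFAULT_PROPERTY_SET,
        feature_selection: bool = True,
        rank_mode: str = "rfe",
        step: int = 50,
        grid_step: int = 50,
        cv_folds: int = 5,
        n_trees: int = 500,
        selection_n_trees: int = 200,
        weights: str | Mapping[str, float] = "optimize",
        threshold: float = 0.5,
        threshold_mode: str = "fixed",
        target_sp: float = 0.80,
        algorithm: str = "rf",
        random_state: int = 0,
    ):
        self.w = w
        self.k_values = k_values
        self.K_values = K_values
        self.property_set = property_set
        self.feature_selection = feature_selection
        self.rank_mode = rank_mode
        self.step = step
        self.grid_step = grid_step
        self.cv_folds = cv_folds
        self.n_trees = n_trees
        self.selection_n_trees = selection_n_trees
        self.weights = weights
        self.threshold = threshold
        self.threshold_mode = threshold_mode
        self.target_sp = target_sp
        self.algorithm = algorithm
        self.random_state = random_state

    def _specs(self) -> dict[str, EncodingSpec]:
        return {
            scheme: EncodingSpec(
                scheme=scheme, w=self.w, k_values=tuple(self.k_values),
                K_values=tuple(self.K_values),
                property_set=tuple(self.property_set),
            )
            for scheme in SCHEMES
        }

    def fit(self, X: Sequence[SiteWindow], y: Sequence[int] | None = None):
        windows = list(X)
        y = labels_array(windows) if y is None else np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise EnsembleError("training labels must contain both classes")
        specs = self._specs()
        tables = load_default_properties()

        matrices = {
            s: encode_dataset(windows, specs[s], tables if s == "aaindex" else None)
            for s in SCHEMES
        }

        subsets: dict[str, SelectedSubset] = {}
        rankings: dict[str, FeatureRanking] = {}
        for s in SCHEMES:
            seed = stage_seed(self.random_state, f"select:{s}")
            if self.feature_selection:
                ranking = rfe_rank(
                    matrices[s], y, step=self.step, seed=seed,
                    n_trees=self.selection_n_trees, mode=self.rank_mode,
                )
                subsets[s] = grid_select(
                    ranking, matrices[s], y, grid_step=self.grid_step,
                    cv_folds=self.cv_folds, seed=seed,
                    n_trees=self.selection_n_trees, scheme=s,
                )
                rankings[s] = ranking
            else:
                names = tuple(matrices[s].columns)
                subsets[s] = SelectedSubset(
                    scheme=s, features=names,
                    grid_scores={len(names): float("nan")},
                    chosen_size=len(names),
                )

        # out-of-fold probabilities per scheme for honest fusion
        folds = stratified_folds(
            y, self.cv_folds, stage_seed(self.random_state, "cv")
        )
        oof = {s: np.full(len(y), np.nan) for s in SCHEMES}
        for fold_id, (tr, te) in enumerate(folds):
            for s in SCHEMES:
                model = train_single(
                    matrices[s].iloc[tr], y[tr], subsets[s],
                    n_trees=self.n_trees,
                    seed=stage_seed(self.random_state, f"fold{fold_id}:{s}"),
                    algorithm=self.algorithm,
                )
                oof[s][te] = predict_single(model, matrices[s].iloc[te])

        if isinstance(self.weights, str) and self.weights == "optimize":
            fusion = optimize_weights(oof, y)
        else:
            fusion = FusionWeights(dict(self.weights))

        fused_oof = fuse_scores(oof, fusion)
        fold_reports = [
            evaluate_scores(fused_oof[te], y[te], threshold=self.threshold)
            for _, te in folds
        ]

        models = {
            s: train_single(
                matrices[s], y, subsets[s], n_trees=self.n_trees,
                seed=stage_seed(self.random_state, f"final:{s}"),
                algorithm=self.algorithm,
            )
            for s in SCHEMES
        }

        if self.threshold_mode == "specificity":
            self.threshold_ = threshold_at_specificity(
                fused_oof, y, self.target_sp
            )
        else:
            self.threshold_ = float(self.threshold)

        self.classes_ = np.array([0, 1])
        self.specs_ = specs
        self.subsets_ = subsets
        self.rankings_ = rankings
        self.weights_ = fusion
        self.oof_scores_ = oof
        self.fused_oof_ = fused_oof
        self.cv_folds_ = folds
        self.cv_reports_ = fold_reports
        self.cv_summary_ = summarize_folds(fold_reports)
        self.ensemble_ = TrainedEnsemble(models=models, fusion=fusion, specs=specs)
        return self

    def decision_scores(self, X: Sequence[SiteWindow]) -> pd.DataFrame:
        if not hasattr(self, "ensemble_"):
            raise EnsembleError("estimator is not fitted")
        return ensemble_predict(self.ensemble_, list(X))

    def predict_proba(self, X: Sequence[SiteWindow]) -> np.ndarray:
        fused = self.decision_scores(X)["score"].to_numpy()
        return np.column_stack([1.0 - fused, fused])

    def predict(self, X: Sequence[SiteWindow]) -> np.ndarray:
        fused = self.decision_scores(X)["score"].to_numpy()
        return (fused >= self.threshold_).astype(int)
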