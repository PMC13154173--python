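"""Boruta all-relevant feature selection and a tuned random-forest classifier.

Boruta compares each bucket's forest importance against "shadow" copies of
the whole matrix with every column independently permuted: a bucket scores
a hit in an iteration when its importance exceeds the chosen percentile of
the shadow importances.  After a fixed number of iterations the hit count
is tested two-sidedly against Bin(n_iter, 1/2) with Bonferroni control over
buckets: significantly many hits confirms the bucket, significantly few
rejects it, anything else stays tentative.

The confirmed buckets feed a random-forest classifier whose hyperparameters
(tree count, depth, minimum impurity decrease, features per split) are
chosen by a seeded random search scored with stratified-CV macro F1; the
fitted forest exposes its Gini importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluate import f1_macro


@dataclass
class BorutaConfig:
    max_iter: int = 100
    percentile: float = 100.0
    alpha: float = 0.05
    n_estimators: int = 100
    max_depth: int | None = 5

    def __post_init__(self) -> None:
        if self.max_iter < 10:
            raise ValueError("max_iter must be at least 10")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class BorutaResult:
    status: np.ndarray       # {"confirmed", "tentative", "rejected"} per feature
    hits: np.ndarray
    n_iterations: int

    @property
    def confirmed(self) -> np.ndarray:
        return np.flatnonzero(self.status == "confirmed")

    @property
    def tentative(self) -> np.ndarray:
        return np.flatnonzero(self.status == "tentative")

    @property
    def rejected(self) -> np.ndarray:
        return np.flatnonzero(self.status == "rejected")

    def table(self, feature_names=None) -> pd.DataFrame:
        names = feature_names if feature_names is not None else np.arange(self.status.size)
        return pd.DataFrame({"feature": names, "hits": self.hits,
                             "iterations": self.n_iterations, "status": self.status})


def boruta_select(X: np.ndarray, labels, config: BorutaConfig | None = None,
                  seed: int = 0) -> BorutaResult:
    """Run the shadow-feature hit-count selection; deterministic given seed."""
    if config is None:
        config = BorutaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in labels])
    n, p = X.shape
    root = np.random.SeedSequence(seed)
    hits = np.zeros(p, dtype=int)
    for it, child in enumerate(root.spawn(config.max_iter)):
        # one child stream per column keeps shadows decoupled from column count
        col_streams = child.spawn(p + 1)
        shadows = np.column_stack([
            np.random.Generator(np.random.Philox(cs)).permutation(X[:, j])
            for j, cs in enumerate(col_streams[:p])])
        rf_seed = int(np.random.Generator(np.random.Philox(col_streams[p])).integers(2 ** 31))
        forest = RandomForestClassifier(n_estimators=config.n_estimators,
                                        max_depth=config.max_depth,
                                        random_state=rf_seed, n_jobs=1)
        forest.fit(np.hstack([X, shadows]), y)
        imp = forest.feature_importances_
        threshold = np.percentile(imp[p:], config.percentile)
        hits += imp[:p] > threshold
    n_iter = config.max_iter
    # two-sided binomial vs Bin(n_iter, 1/2), Bonferroni over the p features
    cut = config.alpha / (2 * p)
    p_high = binom.sf(hits - 1, n_iter, 0.5)
    p_low = binom.cdf(hits, n_iter, 0.5)
    status = np.full(p, "tentative", dtype=object)
    status[p_high < cut] = "confirmed"
    status[p_low < cut] = "rejected"
    return BorutaResult(status.astype(str), hits, n_iter)


@dataclass
class RFCSearchSpace:
    n_estimators: tuple[int, ...] = (100, 200)
    max_depth: tuple[int | None, ...] = (3, 5, 8, 12, None)
    min_impurity_decrease: tuple[float, float] = (1e-6, 1e-2)  # log-uniform range
    max_features: tuple = ("sqrt", "log2", 0.3)
    n_draws: int = 15


@dataclass
class RFCModel:
    forest: RandomForestClassifier
    params: dict
    cv_score: float
    classes_: list[str]
    feature_indices: np.ndarray | None = None
    search_log: list[dict] = field(default_factory=list)

    @property
    def gini_importances(self) -> np.ndarray:
        return self.forest.feature_importances_

    def gini_ranking(self, feature_names=None) -> pd.DataFrame:
        imp = self.gini_importances
        names = feature_names if feature_names is not None else np.arange(imp.size)
        order = np.argsort(-imp, kind="stable")
        return pd.DataFrame({"feature": np.asarray(names)[order], "gini_importance": imp[order]})


def fit_rfc(X: np.ndarray, labels, space: RFCSearchSpace | None = None,
            cv_folds: int = 5, seed: int = 0) -> RFCModel:
    """Seeded random search over forest hyperparameters, scored by CV macro F1."""
    if space is None:
        space = RFCSearchSpace()
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    y = np.asarray([str(v) for v in labels])
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    folds = list(skf.split(X, y))

    best_key, best_score, best_params, log = None, -np.inf, None, []
    for _ in range(space.n_draws):
        params = {
            "n_estimators": int(rng.choice(space.n_estimators)),
            "max_depth": space.max_depth[rng.integers(len(space.max_depth))],
            "min_impurity_decrease": float(np.exp(
                rng.uniform(*np.log(space.min_impurity_decrease)))),
            "max_features": space.max_features[rng.integers(len(space.max_features))],
        }
        fit_seed = int(rng.integers(2 ** 31))
        pred = np.empty(y.shape, dtype=object)
        for tr, va in folds:
            forest = RandomForestClassifier(**params, random_state=fit_seed, n_jobs=1)
            forest.fit(X[tr], y[tr])
            pred[va] = forest.predict(X[va])
        score = f1_macro(list(y), list(pred))
        log.append({**params, "cv_f1": score})
        # CV ties are common on separable data; prefer the richer ensemble
        # (more trees, then deeper, then laxer impurity threshold), whose
        # vote fractions resolve class probabilities more finely
        depth = params["max_depth"]
        key = (score, params["n_estimators"],
               np.inf if depth is None else depth, -params["min_impurity_decrease"])
        if best_key is None or key > best_key:
            best_key, best_score, best_params, best_seed = key, score, params, fit_seed
    forest = RandomForestClassifier(**best_params, random_state=best_seed, n_jobs=1)
    forest.fit(X, y)
    return RFCModel(forest, best_params, best_score, sorted(set(y)), search_log=log)


def predict_proba(model: RFCModel, X_new: np.ndarray) -> np.ndarray:
    """Per-class probability (tree-vote fractions); columns in sorted class order."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if model.feature_indices is not None:
        if X_new.shape[1] != model.feature_indices.size:
            X_new = X_new[:, model.feature_indices]
    proba = model.forest.predict_proba(X_new)
    order = [list(model.forest.classes_).index(c) for c in model.classes_]
    return proba[:, order]


class BorutaRFClassifier:
    """Full stack: standard scaling + Boruta selection + tuned random forest.

    Tentative features are excluded by default; ``include_tentative=True``
    keeps them alongside the confirmed set.  If nothing is confirmed the
    selection falls back to all features (logged in the result).
    """

    def __init__(self, boruta: BorutaConfig | None = None,
                 space: RFCSearchSpace | None = None, cv_folds: int = 5,
                 include_tentative: bool = False, seed: int = 0):
        self.boruta_config = boruta
        self.space = space
        self.cv_folds = cv_folds
        self.include_tentative = include_tentative
        self.seed = seed

    def fit(self, X: np.ndarray, y) -> "BorutaRFClassifier":
        X = np.asarray(X, dtype=float)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd <= 1e-12] = 1.0
        self._sd = sd
        Z = (X - self._mean) / self._sd
        self.selection_ = boruta_select(Z, y, self.boruta_config, seed=self.seed)
        keep = list(self.selection_.confirmed)
        if self.include_tentative:
            keep = sorted(keep + list(self.selection_.tentative))
        self.fallback_all_features_ = len(keep) == 0
        idx = np.arange(Z.shape[1]) if self.fallback_all_features_ else np.asarray(keep)
        self.rfc_ = fit_rfc(Z[:, idx], y, self.space, self.cv_folds, seed=self.seed + 1)
        self.rfc_.feature_indices = idx
        self.classes_ = self.rfc_.classes_
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(np.asarray(X, float)) - self._mean) / self._sd
        return Z[:, self.rfc_.feature_indices]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.rfc_.forest.predict_proba(self._transform(X))
        order = [list(self.rfc_.forest.classes_).index(c) for c in self.classes_]
        return proba[:, order]

    def predict(self, X: np.ndarray) -> list[str]:
        proba = self.predict_proba(X)
        return [self.classes_[int(np.argmax(row))] for row in proba]
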