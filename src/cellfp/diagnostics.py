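"""SIMCA-style evaluation suite for fitted PLS-DA models.

Variable importance in projection (VIP), per-class selectivity ratios,
fold-jackknife confidence intervals on regression coefficients, label
permutation testing of cross-validated F1, and the sensitivity of the model
to removal of top-VIP features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .evaluate import f1_macro
from .plsda import PLSDAModel, fit_plsda, predict_labels


class PLSDAPipeline:
    """Standard scaling + PLS-DA + argmax call, refit as one unit per fold.

    ``tol``/``max_iter`` are forwarded to the NIPALS iteration; a lower cap
    is useful in permutation simulations where the noise spectrum is nearly
    degenerate and the power iteration cannot converge anyway.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-10,
                 max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y) -> "PLSDAPipeline":
        X = np.asarray(X, dtype=float)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd <= 1e-12] = 1.0
        self._sd = sd
        A = min(self.n_components, X.shape[0] - 1, X.shape[1])
        self.model = fit_plsda((X - self._mean) / self._sd, y, A,
                               tol=self.tol, max_iter=self.max_iter)
        return self

    def predict(self, X: np.ndarray) -> list[str]:
        return predict_labels(self.model, (np.asarray(X, float) - self._mean) / self._sd)


def cv_f1(pipeline_factory, X: np.ndarray, y, cv_folds: int = 5,
          seed: int = 0) -> float:
    """Pooled macro F1 over stratified CV folds; the whole pipeline
    (scaling included) is refit inside every fold."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=object)
    for tr, va in skf.split(X, y):
        model = pipeline_factory().fit(X[tr], y[tr])
        pred[va] = model.predict(X[va])
    return f1_macro(list(y), list(pred))


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip(model: PLSDAModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a); mean(VIP^2) = 1."""
    W = model.weights
    p = W.shape[0]
    ssy = model.ssy
    total = ssy.sum()
    if total == 0:
        return np.zeros(p)
    return np.sqrt(p * (W ** 2 @ ssy) / total)


def vip_table(model: PLSDAModel, feature_names=None) -> pd.DataFrame:
    scores = vip(model)
    names = feature_names if feature_names is not None else np.arange(scores.size)
    order = np.argsort(-scores, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, scores.size + 1)
    return pd.DataFrame({"feature": names, "vip": scores, "rank": rank})


# ---------------------------------------------------------------------------
# Selectivity ratio
# ---------------------------------------------------------------------------

def selectivity_ratio(model: PLSDAModel, X: np.ndarray,
                      class_k: int | str | None = None) -> np.ndarray:
    """Target-projection selectivity ratio per feature.

    For class k the target direction is b_k/||b_k||; each feature column is
    split into the part explained by the target-projection score and the
    orthogonal residual, and SR_j is the ratio of the two squared norms.
    Columns fully explained get an +inf sentinel.  Returns a (p,) array for
    one class, or (p, K) when class_k is None.
    """
    if class_k is None:
        return np.column_stack([selectivity_ratio(model, X, k)
                                for k in range(len(model.encoding.classes))])
    if isinstance(class_k, str):
        class_k = model.encoding.classes.index(class_k)
    Xc = np.asarray(X, float) - model.x_mean
    b = model.coef[:, class_k]
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("regression coefficients for this class are all zero")
    t = Xc @ (b / nb)
    tt = float(t @ t)
    p_tp = Xc.T @ t / tt
    explained = np.outer(t, p_tp)
    resid = Xc - explained
    num = (explained ** 2).sum(axis=0)
    den = (resid ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(den <= np.finfo(float).eps * max(num.max(), 1.0),
                      np.inf, num / den)
    return np.where(num == 0.0, 0.0, sr)


def sr_table(model: PLSDAModel, X: np.ndarray, feature_names=None) -> pd.DataFrame:
    """Per-class SR table; +inf sentinels capped at the largest finite value."""
    sr = selectivity_ratio(model, X)
    finite = sr[np.isfinite(sr)]
    cap = float(finite.max()) if finite.size else 1.0
    sr = np.where(np.isfinite(sr), sr, cap)
    names = feature_names if feature_names is not None else np.arange(sr.shape[0])
    out = pd.DataFrame(sr, columns=model.encoding.classes)
    out.insert(0, "feature", names)
    return out


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    estimate: np.ndarray   # p x K full-data coefficients
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    stable: np.ndarray     # CI excludes zero
    classes: list[str]

    def table(self, class_name: str, feature_names=None) -> pd.DataFrame:
        k = self.classes.index(class_name)
        names = feature_names if feature_names is not None else np.arange(self.estimate.shape[0])
        return pd.DataFrame({"feature": names, "coef": self.estimate[:, k],
                             "se": self.se[:, k], "ci_low": self.ci_low[:, k],
                             "ci_high": self.ci_high[:, k], "stable": self.stable[:, k]})


def jackknife_ci(X: np.ndarray, labels, n_components: int = 2, n_folds: int = 5,
                 level: float = 0.95, seed: int = 0) -> JackknifeResult:
    """Delete-one-fold jackknife on the PLS-DA coefficient matrix.

    The model is refit on each stratified fold-complement; the d-fold
    jackknife SE sqrt(((m-1)/m) * sum_i (B_i - Bbar)^2) feeds a
    normal-approximation CI around the full-data estimate.
    """
    X = np.asarray(X, float)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValueError(f"smallest class ({counts.min()}) below fold count {n_folds}")
    full = fit_plsda(X, y, n_components)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reps = []
    for tr, _ in skf.split(X, y):
        reps.append(fit_plsda(X[tr], y[tr], n_components).coef)
    reps = np.stack(reps)
    m = n_folds
    se = np.sqrt((m - 1) / m * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    z = float(norm.ppf(0.5 + level / 2))
    lo, hi = full.coef - z * se, full.coef + z * se
    stable = (lo > 0) | (hi < 0)
    return JackknifeResult(full.coef, se, lo, hi, stable, list(full.encoding.classes))


# ---------------------------------------------------------------------------
# Permutation testing
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    observed: float
    null_scores: np.ndarray
    p_value: float
    n_permutations: int


def permutation_test(pipeline_factory, X: np.ndarray, labels, n_perm: int = 999,
                     cv_folds: int = 5, seed: int = 0) -> PermutationTestResult:
    """Test the CV F1 against the null of label exchangeability.

    Labels are permuted globally; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    fold_seed = int(rng.integers(2 ** 31))
    observed = cv_f1(pipeline_factory, X, y, cv_folds, seed=fold_seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y.size)
        null[b] = cv_f1(pipeline_factory, X, y[perm], cv_folds,
                        seed=int(rng.integers(2 ** 31)))
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationTestResult(observed, null, p, n_perm)


# ---------------------------------------------------------------------------
# VIP-removal sensitivity
# ---------------------------------------------------------------------------

def vip_removal_sensitivity(X: np.ndarray, labels, n_components: int = 2,
                            max_removed_fraction: float = 0.25, step: int = 5,
                            cv_folds: int = 5, seed: int = 0,
                            recompute: bool = False) -> pd.DataFrame:
    """CV F1 as top-VIP features are removed.

    By default the removal order is frozen at the baseline ranking; with
    ``recompute=True`` the VIP ranking is re-evaluated after each removal
    round.  The curve has floor(max_removed_fraction * p / step) + 1 points.
    """
    X = np.asarray(X, float)
    y = np.asarray(labels)
    p = X.shape[1]
    factory = lambda: PLSDAPipeline(n_components)  # noqa: E731
    n_steps = int(math.floor(max_removed_fraction * p / step)) + 1

    baseline_model = PLSDAPipeline(n_components).fit(X, y).model
    order = np.argsort(-vip(baseline_model), kind="stable")

    rows = []
    removed: list[int] = []
    remaining = list(range(p))
    for s_i in range(n_steps):
        n_removed = s_i * step
        while len(removed) < n_removed:
            if recompute and removed:
                sub_model = PLSDAPipeline(n_components).fit(X[:, remaining], y).model
                sub_order = np.argsort(-vip(sub_model), kind="stable")
                target = remaining[sub_order[0]]
            else:
                target = next(j for j in order if j not in removed)
            removed.append(int(target))
            remaining.remove(int(target))
        score = cv_f1(factory, X[:, remaining], y, cv_folds, seed=seed)
        rows.append({"n_removed": n_removed, "cv_f1": score})
    return pd.DataFrame(rows)
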