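"""Soft-margin SVM on PLS-DA latent scores with stochastic hyperparameter search.

The latent projection compresses the bucketed spectra into a few components
where class covariance is maximal; the SVM then draws the decision
boundaries in that space.  Hyperparameters (kernel, C, gamma) are chosen by
a seeded random search scored with stratified-CV macro F1.

Class probabilities follow the classic one-vs-one construction: each class
pair gets a binary SVM whose decision values are Platt-scaled (a sigmoid
fitted to cross-validated decision values with regularized targets), and
the pairwise probabilities are coupled into a single simplex vector by the
Wu-Lin-Weng iteration.  Probabilities are therefore monotone in each
pairwise decision value and rows sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluate import f1_macro
from .plsda import PLSDAModel, fit_plsda, project

logger = logging.getLogger(__name__)


def _platt_fit(decision: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """Fit p(pos | d) = 1 / (1 + exp(A d + B)) with Platt's regularized targets."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    t = np.where(positive, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        z = params[0] * decision + params[1]
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll, x0, method="BFGS")
    return float(res.x[0]), float(res.x[1])


def _platt_apply(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * decision + b
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def pairwise_coupling(r: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Couple pairwise probabilities r[i, j] = p(class i | i or j) into a
    probability vector (Wu, Lin & Weng's second method, as used by LIBSVM)."""
    K = r.shape[0]
    Q = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i == j:
                Q[i, i] = sum(r[j2, i] ** 2 for j2 in range(K) if j2 != i)
            else:
                Q[i, j] = -r[j, i] * r[i, j]
    p = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        pQp = float(p @ Q @ p)
        diff = 0.0
        for t_i in range(K):
            new = (-(Q[t_i] @ p) + Q[t_i, t_i] * p[t_i] + pQp) / Q[t_i, t_i]
            diff = max(diff, abs(new - p[t_i]))
            p[t_i] = new
            p /= p.sum()
            pQp = float(p @ Q @ p)
        if diff < tol:
            break
    return p


@dataclass
class SVMSearchSpace:
    kernels: tuple[str, ...] = ("linear", "rbf")
    c_range: tuple[float, float] = (1e-2, 1e3)
    gamma_range: tuple[float, float] = (1e-3, 1e1)
    n_draws: int = 60

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for lo, hi in (self.c_range, self.gamma_range):
            if lo <= 0 or hi < lo:
                raise ValueError("hyperparameter ranges must be positive and ordered")

    def draw(self, rng: np.random.Generator) -> dict:
        kernel = self.kernels[rng.integers(len(self.kernels))]
        params = {"kernel": kernel,
                  "C": float(np.exp(rng.uniform(*np.log(self.c_range))))}
        if kernel == "rbf":
            params["gamma"] = float(np.exp(rng.uniform(*np.log(self.gamma_range))))
        return params


@dataclass
class _PairMachine:
    svc: SVC
    platt_a: float
    platt_b: float


@dataclass
class LatentSVMModel:
    machines: dict[tuple[int, int], _PairMachine]
    params: dict
    cv_score: float
    classes_: list[str]
    plsda: PLSDAModel | None = None
    scaler: object | None = None
    search_log: list[dict] = field(default_factory=list)

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        K = len(self.classes_)
        n = scores.shape[0]
        pair_p = {}
        for (i, j), m in self.machines.items():
            d = m.svc.decision_function(scores)
            pair_p[(i, j)] = _platt_apply(d, m.platt_a, m.platt_b)
        out = np.empty((n, K))
        r = np.full((K, K), 0.5)
        for row in range(n):
            for (i, j), pij in pair_p.items():
                # clip away exact 0/1 so the coupling system stays solvable
                p = float(np.clip(pij[row], 1e-7, 1 - 1e-7))
                r[i, j], r[j, i] = p, 1.0 - p
            out[row] = pairwise_coupling(r)
        return out

    def predict(self, scores: np.ndarray) -> list[str]:
        proba = self.predict_proba(scores)
        return [self.classes_[int(np.argmax(row))] for row in proba]


def fit_latent_svm(scores: np.ndarray, labels, space: SVMSearchSpace | None = None,
                   cv_folds: int = 5, seed: int = 0) -> LatentSVMModel:
    """Random-search an SVM on latent scores; refit the best with one-vs-one
    Platt-scaled probability machinery."""
    if space is None:
        space = SVMSearchSpace()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([str(v) for v in labels])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    folds = list(skf.split(scores, y))

    best_score, best_params, search_log = -np.inf, None, []
    for _ in range(space.n_draws):
        params = space.draw(rng)
        pred = np.empty(y.shape, dtype=object)
        for tr, va in folds:
            clf = SVC(**params)
            clf.fit(scores[tr], y[tr])
            pred[va] = clf.predict(scores[va])
        score = f1_macro(list(y), list(pred))
        search_log.append({**params, "cv_f1": score})
        if score > best_score:  # strict: first best wins on ties
            best_score, best_params = score, params

    # one binary machine per class pair; sigmoid fitted to cross-validated
    # decision values so the calibration never sees its own training fits
    machines = {}
    for i, j in combinations(range(len(classes)), 2):
        mask = (y == classes[i]) | (y == classes[j])
        Xp, yp = scores[mask], y[mask]
        positive = yp == classes[i]
        n_splits = min(cv_folds, int(positive.sum()), int((~positive).sum()))
        cv_decision = np.empty(yp.size)
        if n_splits >= 2:
            pair_skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                       random_state=int(rng.integers(2 ** 31)))
            for tr, va in pair_skf.split(Xp, yp):
                sub = SVC(**best_params).fit(Xp[tr], yp[tr])
                sign = 1.0 if sub.classes_[1] == classes[i] else -1.0
                cv_decision[va] = sign * sub.decision_function(Xp[va])
        svc = SVC(**best_params).fit(Xp, yp)
        sign = 1.0 if svc.classes_[1] == classes[i] else -1.0
        if n_splits < 2:
            cv_decision = sign * svc.decision_function(Xp)
        a, b = _platt_fit(cv_decision, positive)
        if sign < 0:  # fold the orientation into the sigmoid slope
            a, b = -a, b
        machines[(i, j)] = _PairMachine(svc, a, b)
    return LatentSVMModel(machines, best_params, best_score, classes,
                          search_log=search_log)


class PLSDASVMClassifier:
    """Full stack: standard scaling + PLS-DA projection + latent SVM.

    Operates on raw (PQN-normalized) feature rows; all training-derived
    state (scaler, projection, boundaries) comes from ``fit`` only.
    """

    def __init__(self, n_components: int = 2, space: SVMSearchSpace | None = None,
                 cv_folds: int = 5, seed: int = 0):
        self.n_components = n_components
        self.space = space
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X: np.ndarray, y) -> "PLSDASVMClassifier":
        X = np.asarray(X, dtype=float)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd <= 1e-12] = 1.0
        self._sd = sd
        Z = (X - self._mean) / self._sd
        A = min(self.n_components, X.shape[0] - 1, X.shape[1])
        self.plsda_ = fit_plsda(Z, y, A)
        T = project(self.plsda_, Z)
        self.latent_ = fit_latent_svm(T, y, self.space, self.cv_folds, self.seed)
        self.classes_ = self.latent_.classes_
        return self

    def _scores(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(np.asarray(X, float)) - self._mean) / self._sd
        return project(self.plsda_, Z)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.latent_.predict_proba(self._scores(X))

    def predict(self, X: np.ndarray) -> list[str]:
        proba = self.predict_proba(X)
        # argmax with lexicographic tie-break (classes_ is sorted)
        ties = np.isclose(proba, proba.max(axis=1, keepdims=True))
        if np.any(ties.sum(axis=1) > 1):
            logger.info("probability tie broken by lexicographic class order")
        return [self.classes_[int(np.argmax(row))] for row in proba]
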