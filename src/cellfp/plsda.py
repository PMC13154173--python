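"""NIPALS PLS2 discriminant analysis and a PCA baseline.

PLS-DA regresses a column-centered one-hot class indicator matrix Y on the
(scaled) feature matrix X.  Components are extracted one at a time by the
NIPALS power iteration: the weight vector w maximizes the covariance of the
score t = Xw with Y, and X and Y are deflated by the rank-one fit t p' and
t q' so successive scores are mutually orthogonal.  The regression
coefficient matrix B = W (P'W)^-1 Q' maps original features to class
predictions and underlies every diagnostic downstream (VIP, selectivity
ratio, jackknife).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2


@dataclass
class ClassEncoding:
    classes: list[str]
    indicator: np.ndarray       # raw one-hot, n x K
    column_means: np.ndarray    # K

    @classmethod
    def from_labels(cls, labels) -> "ClassEncoding":
        labels = list(labels)
        names = sorted(set(labels))
        if len(names) < 2:
            raise ValueError("need at least two classes")
        index = {c: j for j, c in enumerate(names)}
        Y = np.zeros((len(labels), len(names)))
        for i, lab in enumerate(labels):
            Y[i, index[lab]] = 1.0
        return cls(names, Y, Y.mean(axis=0))


@dataclass
class PLSDAModel:
    n_components: int
    weights: np.ndarray        # W, p x A, unit columns
    x_loadings: np.ndarray     # P, p x A
    y_loadings: np.ndarray     # Q, K x A (regression loadings)
    scores: np.ndarray         # T, n x A
    coef: np.ndarray           # B, p x K
    ssy: np.ndarray            # per-component Y-variance share ||t||^2 ||q||^2
    x_mean: np.ndarray
    encoding: ClassEncoding

    @property
    def rotations(self) -> np.ndarray:
        """R = W (P'W)^-1 so that T = (X - mean) R."""
        return self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)


def fit_plsda(X: np.ndarray, labels, n_components: int = 2,
              tol: float = 1e-10, max_iter: int = 500) -> PLSDAModel:
    """Fit NIPALS PLS2 on X against centered one-hot labels.

    Deterministic: the u-iteration starts from the centered Y column of
    maximal variance (ties broken by lowest index).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    enc = ClassEncoding.from_labels(labels)
    if len(enc.classes) < 2:
        raise ValueError("need at least two classes")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    Yc = enc.indicator - enc.column_means

    A = n_components
    K = len(enc.classes)
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((K, A))
    T = np.zeros((n, A))
    ssy = np.zeros(A)

    for a in range(A):
        col_var = Yc.var(axis=0)
        u = Yc[:, int(np.argmax(col_var))].copy()
        w_old = np.zeros(p)
        for _ in range(max_iter):
            w = Xc.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("X deflated to zero before requested components")
            w /= nw
            t = Xc @ w
            qd = Yc.T @ t
            nq = np.linalg.norm(qd)
            if nq == 0:
                break
            u = Yc @ (qd / nq)
            # w has unit norm, so the change is an absolute convergence measure
            if np.linalg.norm(w - w_old) <= tol:
                break
            w_old = w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("degenerate component with zero score variance")
        p_a = Xc.T @ t / tt
        q_a = Yc.T @ t / tt
        Xc = Xc - np.outer(t, p_a)
        Yc = Yc - np.outer(t, q_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
        ssy[a] = tt * float(q_a @ q_a)

    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSDAModel(A, W, P, Q, T, B, ssy, x_mean, enc)


def project(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Latent scores of new (scaled) samples; reproduces T on training X."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.weights.shape[0]:
        raise ValueError(f"expected {model.weights.shape[0]} features, got {X_new.shape[1]}")
    return (X_new - model.x_mean) @ model.rotations


def predict_continuous(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous class indicators Yhat = (X - mean) B + Y column means."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coef.shape[0]:
        raise ValueError(f"expected {model.coef.shape[0]} features, got {X_new.shape[1]}")
    return (X_new - model.x_mean) @ model.coef + model.encoding.column_means


def predict_labels(model: PLSDAModel, X_new: np.ndarray) -> list[str]:
    """Diagnostic argmax class call from the continuous prediction."""
    yhat = predict_continuous(model, X_new)
    return [model.encoding.classes[j] for j in np.argmax(yhat, axis=1)]


@dataclass
class PCAResult:
    loadings: np.ndarray                # p x A right singular vectors
    scores: np.ndarray                  # n x A
    explained_variance_ratio: np.ndarray


def fit_pca(X: np.ndarray, n_components: int = 2) -> PCAResult:
    """PCA by SVD of the centered matrix; EVR_i = sigma_i^2 / sum sigma^2."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    A = min(n_components, s.size)
    # deterministic sign: largest-magnitude loading element positive
    V = Vt[:A].T
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(A)])
    signs[signs == 0] = 1.0
    V = V * signs
    scores = Xc @ V
    total = float((s ** 2).sum())
    evr = (s[:A] ** 2) / total if total > 0 else np.zeros(A)
    return PCAResult(V, scores, evr)


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95
                       ) -> tuple[np.ndarray, float, float, float]:
    """95% (by default) covariance ellipse of 2-D scores.

    Returns (center, semi_major, semi_minor, angle_rad) using the
    chi-square(2) radius, for score-plot overlays.
    """
    S = np.atleast_2d(scores_2d)
    if S.shape[1] != 2:
        raise ValueError("expected n x 2 scores")
    center = S.mean(axis=0)
    cov = np.cov(S.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r = float(chi2.ppf(level, df=2))
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return center, float(np.sqrt(r * evals[0])), float(np.sqrt(r * evals[1])), angle
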