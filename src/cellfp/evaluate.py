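"""Scoring, mixed-sample assignment, cross-field transfer and attributions.

Mixtures of two cell types are never a training class: a model trained on
pure classes predicts per-class probabilities and the mixture is called as
the unordered pair of the two highest-probability pure classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

logger = logging.getLogger(__name__)


def f1_macro(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    """Unweighted mean of per-class F1 over the classes present in the truth.

    Per-class F1 = 2PR/(P+R), defined as 0 when precision + recall = 0.
    """
    if len(true_labels) == 0:
        raise ValueError("empty input")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("length mismatch")
    classes = sorted(set(true_labels))
    return float(_sk_f1(list(true_labels), list(predicted_labels), labels=classes,
                        average="macro", zero_division=0))


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              class_order: Sequence[str] | None = None) -> pd.DataFrame:
    """K x K counts, truth in rows, prediction in columns."""
    if class_order is None:
        class_order = sorted(set(true_labels) | set(predicted_labels))
    mat = _sk_confusion(list(true_labels), list(predicted_labels), labels=list(class_order))
    return pd.DataFrame(mat, index=list(class_order), columns=list(class_order))


def pair_str(a: str, b: str) -> str:
    """Canonical serialized form of an unordered class pair."""
    if a == b:
        raise ValueError("pair members must differ")
    first, second = sorted((a, b))
    return f"{first}+{second}"


def assign_pair(probabilities: Sequence[float], class_order: Sequence[str]) -> str:
    """Unordered pair of the two highest-probability classes.

    Exact ties are broken by position in ``class_order`` (logged).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size < 2 or len(class_order) != p.size:
        raise ValueError("need probabilities for at least two classes")
    order = np.lexsort((np.arange(p.size), -p))  # stable: prob desc, then class order
    top2 = order[:2]
    if p.size > 2 and p[order[1]] == p[order[2]]:
        logger.info("exact probability tie broken by class order: %s",
                    [class_order[i] for i in order[1:3]])
    return pair_str(class_order[top2[0]], class_order[top2[1]])


@dataclass
class MixtureEvaluation:
    predicted_pairs: list[str]
    true_pairs: list[str]
    pair_f1: float
    confusion: pd.DataFrame


def evaluate_mixtures(model, X_mixed: np.ndarray,
                      true_pairs: Sequence[str]) -> MixtureEvaluation:
    """Score top-2 pair assignment of a pure-class model on mixed samples.

    ``model`` must expose ``predict_proba`` and ``classes_`` and have been
    trained on pure classes only; every true pair must be drawn from them.
    """
    classes = list(model.classes_)
    for tp in true_pairs:
        a, b = tp.split("+")
        if a not in classes or b not in classes:
            raise ValueError(f"true pair {tp!r} references an untrained class")
    proba = model.predict_proba(np.asarray(X_mixed, float))
    predicted = [assign_pair(row, classes) for row in proba]
    truth = [pair_str(*tp.split("+")) for tp in true_pairs]
    return MixtureEvaluation(predicted, truth, f1_macro(truth, predicted),
                             confusion(truth, predicted))


def cross_field_eval(model_factory: Callable[[], object], train_X: np.ndarray,
                     train_y: Sequence[str],
                     test_sets: Mapping[float, tuple[np.ndarray, Sequence[str]]]
                     ) -> pd.DataFrame:
    """Train once (at the reference field) and score at every test field.

    ``model_factory`` builds a fresh estimator with fit/predict; any scaling
    lives inside the estimator so its parameters come from the training
    field only.  All sets must share the bucket grid (same column count).
    """
    train_X = np.asarray(train_X, float)
    model = model_factory()
    model.fit(train_X, list(train_y))
    rows = []
    for field_mhz, (X, y) in test_sets.items():
        X = np.asarray(X, float)
        if X.shape[1] != train_X.shape[1]:
            raise ValueError(f"bucket grid at {field_mhz} MHz differs from training grid")
        pred = model.predict(X)
        rows.append({"field_mhz": field_mhz, "f1": f1_macro(list(y), list(pred)),
                     "n": X.shape[0]})
    return pd.DataFrame(rows)


@dataclass
class ShapleyAttribution:
    attributions: np.ndarray
    mc_sd: np.ndarray
    base_value: float
    prediction: float

    def local_accuracy_gap(self) -> float:
        return float(abs(self.base_value + self.attributions.sum() - self.prediction))


def mc_shapley(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
               background: np.ndarray, n_permutations: int = 200,
               seed: int = 0) -> ShapleyAttribution:
    """Permutation-sampling Shapley attribution of a scalar model output.

    For each random feature ordering, features are switched one by one from
    a randomly drawn background row to the explained sample and the marginal
    change in f is credited to the switched feature.  The attribution sums
    plus the base value (mean f over the sampled background rows) equal f(x)
    exactly by construction; ``mc_sd`` is the Monte-Carlo standard error per
    feature.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be at least 10")
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    p = x.size
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_permutations, p))
    base_vals = np.empty(n_permutations)
    fx = None
    for b in range(n_permutations):
        order = rng.permutation(p)
        z = background[rng.integers(background.shape[0])]
        # build the p+1 intermediate rows and evaluate f in one call
        rows = np.tile(z, (p + 1, 1))
        cur = z.copy()
        for step, j in enumerate(order, start=1):
            cur[j] = x[j]
            rows[step] = cur
        vals = np.asarray(f(rows), dtype=float).ravel()
        contrib[b, order] = np.diff(vals)
        base_vals[b] = vals[0]
        fx = vals[-1]
    attributions = contrib.mean(axis=0)
    mc_sd = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return ShapleyAttribution(attributions, mc_sd, float(base_vals.mean()), float(fx))


def exact_shapley(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                  background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full enumeration of feature orderings.

    Brute-force oracle for small p (p! orderings x background rows).
    """
    from itertools import permutations

    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    total = np.zeros(p)
    count = 0
    for z in background:
        for order in permutations(range(p)):
            rows = np.tile(z, (p + 1, 1))
            cur = z.copy()
            for step, j in enumerate(order, start=1):
                cur[j] = x[j]
                rows[step] = cur
            vals = np.asarray(f(rows), dtype=float).ravel()
            total[list(order)] += np.diff(vals)
            count += 1
    return total / count
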