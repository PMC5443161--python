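"""Candidate classification algorithms with one fit/predict contract.

Five algorithms are available, all exposing calibrated posterior
probabilities so downstream fusion can consume them interchangeably:

LPGM
    Linear probabilistic Gaussian model: unimodal Gaussian
    class-conditionals sharing one pooled covariance matrix; posteriors
    by Bayes' theorem.  The shared covariance yields linear boundaries.
SVM
    Support vector machine with an RBF kernel (``sklearn.svm.SVC``),
    box penalty C = 1, kernel width from the median pairwise-distance
    heuristic, Platt-calibrated probabilities.
FLDA
    Fisher linear discriminant: project features onto the 1-D Fisher
    direction, then run LPGM on the projected scalars.
LR
    Maximum-likelihood logistic regression
    (``sklearn.linear_model.LogisticRegression``).
RLS
    Regularized least squares: one-vs-rest ridge regression on +/-1
    targets, ridge weight lambda selected by internal stratified 5-fold
    CV over a candidate grid (ties resolved toward the larger lambda,
    favouring shrinkage); scores mapped to probabilities by softmax.

The decomposition and ensemble layers never branch on the algorithm id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import ordered_labels

__all__ = [
    "ALGORITHMS",
    "RLSConfig",
    "TrainedClassifier",
    "train",
    "predict_proba",
]

#: Canonical algorithm order; earlier entries win validation-accuracy ties.
ALGORITHMS = ("LPGM", "SVM", "FLDA", "LR", "RLS")

#: Candidate ridge weights for RLS.
DEFAULT_RLS_LAMBDAS = (0.0, 0.5, 1.0, 10.0, 1e2, 1e3, 1e4, 1e5)

# Pooled-covariance ridge for LPGM/FLDA: features can degenerate on
# small subsampled folds (T' as low as 2).
_COV_RIDGE = 1e-6


@dataclass(frozen=True)
class RLSConfig:
    lambda_candidates: tuple[float, ...] = DEFAULT_RLS_LAMBDAS

    def __post_init__(self) -> None:
        if len(self.lambda_candidates) == 0:
            raise ValueError("lambda_candidates must be non-empty")


@dataclass
class TrainedClassifier:
    """A fitted algorithm plus the label set it predicts over."""

    algorithm_id: str
    classes: list[str]
    _impl: object
    validation_accuracy: float | None = None
    meta: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        idx = np.argmax(p, axis=1)  # first max wins -> canonical tie-break
        return np.array([self.classes[i] for i in idx], dtype=object)


# ------------------------------------------------------------------ LPGM

class _LPGM:
    """Pooled-covariance Gaussian class-conditionals + Bayes posterior."""

    def fit(self, X: np.ndarray, y_idx: np.ndarray, n_classes: int) -> "_LPGM":
        d = X.shape[1]
        self.means = np.zeros((n_classes, d))
        self.log_priors = np.zeros(n_classes)
        cov = np.zeros((d, d))
        for c in range(n_classes):
            Xc = X[y_idx == c]
            self.means[c] = Xc.mean(axis=0)
            self.log_priors[c] = np.log(len(Xc) / len(X))
            r = Xc - self.means[c]
            cov += r.T @ r
        cov /= max(len(X) - n_classes, 1)
        cov += _COV_RIDGE * (np.trace(cov) / d + 1e-300) * np.eye(d)
        cov += 1e-12 * np.eye(d)
        self.prec = np.linalg.inv(cov)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        # Linear discriminant scores; shared quadratic term cancels in
        # the posterior so it is omitted.
        A = self.prec @ self.means.T                      # (d, C)
        b = -0.5 * np.einsum("cd,dc->c", self.means, A) + self.log_priors
        return X @ A + b


# ------------------------------------------------------------------ FLDA

class _FLDA:
    """Fisher 1-D projection followed by LPGM on the projected scalars."""

    def fit(self, X: np.ndarray, y_idx: np.ndarray, n_classes: int) -> "_FLDA":
        d = X.shape[1]
        grand = X.mean(axis=0)
        S_b = np.zeros((d, d))
        S_w = np.zeros((d, d))
        for c in range(n_classes):
            Xc = X[y_idx == c]
            m = Xc.mean(axis=0)
            dv = (m - grand)[:, None]
            S_b += len(Xc) * (dv @ dv.T)
            r = Xc - m
            S_w += r.T @ r
        S_w += _COV_RIDGE * (np.trace(S_w) / d + 1e-300) * np.eye(d)
        S_w += 1e-12 * np.eye(d)
        from scipy.linalg import eigh
        evals, evecs = eigh((S_b + S_b.T) / 2, (S_w + S_w.T) / 2)
        w = evecs[:, np.argmax(evals)]
        w = w / np.linalg.norm(w)
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        self.w = w
        self.head = _LPGM().fit(X @ w[:, None], y_idx, n_classes)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.head.decision_scores(X @ self.w[:, None])


# ------------------------------------------------------------------- RLS

class _RLS:
    """One-vs-rest ridge with internal lambda CV; softmax probabilities."""

    def __init__(self, lambdas: Sequence[float], seed: int):
        self.lambdas = tuple(lambdas)
        self.seed = seed

    def fit(self, X: np.ndarray, y_idx: np.ndarray, n_classes: int) -> "_RLS":
        if len(self.lambdas) == 1:
            self.lambda_ = self.lambdas[0]
        else:
            self.lambda_ = self._select_lambda(X, y_idx, n_classes)
        self.W, self.b = self._solve(X, y_idx, n_classes, self.lambda_)
        return self

    @staticmethod
    def _solve(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
               lam: float) -> tuple[np.ndarray, np.ndarray]:
        # Centered ridge; intercept absorbs the means.
        mu = X.mean(axis=0)
        Xc = X - mu
        Y = -np.ones((len(X), n_classes))
        Y[np.arange(len(X)), y_idx] = 1.0
        Yc = Y - Y.mean(axis=0)
        d = X.shape[1]
        G = Xc.T @ Xc + lam * np.eye(d)
        try:
            W = np.linalg.solve(G, Xc.T @ Yc)
        except np.linalg.LinAlgError:
            W = np.linalg.lstsq(G, Xc.T @ Yc, rcond=None)[0]
        if not np.all(np.isfinite(W)):
            W = np.linalg.lstsq(G, Xc.T @ Yc, rcond=None)[0]
        b = Y.mean(axis=0) - mu @ W
        return W, b

    def _select_lambda(self, X: np.ndarray, y_idx: np.ndarray,
                       n_classes: int) -> float:
        counts = np.bincount(y_idx, minlength=n_classes)
        n_folds = int(min(5, counts[counts > 0].min()))
        if n_folds < 2:
            return max(self.lambdas)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=self.seed)
        accs = np.zeros(len(self.lambdas))
        for tr, va in skf.split(X, y_idx):
            for j, lam in enumerate(self.lambdas):
                W, b = self._solve(X[tr], y_idx[tr], n_classes, lam)
                pred = np.argmax(X[va] @ W + b, axis=1)
                accs[j] += np.mean(pred == y_idx[va])
        # ties to the larger lambda (favour shrinkage)
        best = max(range(len(self.lambdas)),
                   key=lambda j: (accs[j], self.lambdas[j]))
        return self.lambdas[best]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W + self.b


# --------------------------------------------------------------- sklearn

class _Sklearn:
    def __init__(self, est):
        self.est = est

    def fit(self, X: np.ndarray, y_idx: np.ndarray, n_classes: int) -> "_Sklearn":
        self.est.fit(X, y_idx)
        self.fitted_classes = np.asarray(self.est.classes_, dtype=int)
        self.n_classes = n_classes
        return self

    def proba(self, X: np.ndarray) -> np.ndarray:
        p_fit = self.est.predict_proba(X)
        p = np.zeros((len(X), self.n_classes))
        p[:, self.fitted_classes] = p_fit
        return p


def _median_heuristic_gamma(X: np.ndarray) -> float:
    n = len(X)
    if n > 400:  # subsample for the O(n^2) distance matrix
        rng = np.random.default_rng(0)
        X = X[rng.choice(n, 400, replace=False)]
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med**2)


def _softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------- API

def train(
    algorithm_id: str,
    X: np.ndarray,
    y: Sequence[str],
    seed: int = 0,
    rls_config: RLSConfig | None = None,
) -> TrainedClassifier:
    """Fit one candidate algorithm on a feature table.

    Parameters
    ----------
    algorithm_id : {"LPGM", "SVM", "FLDA", "LR", "RLS"}
    X : ndarray, shape (n_samples, n_features)
    y : label strings (>= 2 classes, >= 2 samples each)
    seed : int
        Seeds the SVM/LR optimizers and the RLS lambda CV.
    """
    if algorithm_id not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n_samples, n_features) matching y")
    classes = ordered_labels(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    lut = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lut[v] for v in y])
    for c, i in lut.items():
        if np.sum(y_idx == i) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")

    if algorithm_id == "LPGM":
        impl = _LPGM().fit(X, y_idx, len(classes))
    elif algorithm_id == "FLDA":
        impl = _FLDA().fit(X, y_idx, len(classes))
    elif algorithm_id == "RLS":
        cfg = rls_config or RLSConfig()
        impl = _RLS(cfg.lambda_candidates, seed).fit(X, y_idx, len(classes))
    elif algorithm_id == "SVM":
        est = SVC(kernel="rbf", C=1.0, gamma=_median_heuristic_gamma(X),
                  probability=True, random_state=seed)
        with warnings.catch_warnings():
            # Platt scaling via probability=True is the intended design
            warnings.simplefilter("ignore", FutureWarning)
            impl = _Sklearn(est).fit(X, y_idx, len(classes))
    else:  # LR
        est = LogisticRegression(max_iter=2000, random_state=seed)
        impl = _Sklearn(est).fit(X, y_idx, len(classes))
    return TrainedClassifier(algorithm_id=algorithm_id, classes=classes,
                             _impl=impl)


def predict_proba(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Posterior probabilities, rows on the simplex over ``model.classes``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    impl = model._impl
    if isinstance(impl, _Sklearn):
        exp_d = impl.est.n_features_in_
        if X.shape[1] != exp_d:
            raise ValueError(f"expected {exp_d} features, got {X.shape[1]}")
        p = impl.proba(X)
    else:
        scores = impl.decision_scores(X)
        p = _softmax(scores)
    # numerical guard: renormalize exactly
    p = np.clip(p, 1e-300, None)
    return p / p.sum(axis=1, keepdims=True)
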