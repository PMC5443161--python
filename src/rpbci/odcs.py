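"""Ordered diversified classifier system (ODCS).

For every binary sub-problem of a decomposition, each candidate
classification algorithm is trained and scored by seeded stratified
cross-validation on that problem's training features; the candidates
are then ordered by decreasing validation accuracy (VA).  At prediction
time the top-m candidates' posteriors are combined by the reliability
weighted average (RWA)

    P(C_j | x) = sum_i  omega_i  p_i(C_j | x),
    omega_i = exp(VA_i) / sum_k exp(VA_k),

so m = 1 reduces to selection of the single best algorithm and equal
VAs reduce to plain averaging.  The layer is scheme-agnostic: it works
with any binary decomposition, though the reference configuration pairs
it with the DDAG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from ._utils import derive_seed
from .core import ordered_labels
from .multiclass import DecompositionScheme, classify, required_problems

__all__ = [
    "OrderedClassifierList",
    "FusionWeights",
    "order_classifiers",
    "rwa_fuse",
    "softmax_weights",
    "node_posterior",
    "odcs_classify",
]


@dataclass
class OrderedClassifierList:
    """Per-problem candidates sorted by descending validation accuracy."""

    pair_id: str
    entries: list[tuple[clf.TrainedClassifier, float]]
    m_best: int = 1

    def __post_init__(self) -> None:
        vas = [va for _, va in self.entries]
        if any(vas[i] < vas[i + 1] for i in range(len(vas) - 1)):
            raise ValueError("entries must be sorted by non-increasing VA")
        if not (1 <= self.m_best <= len(self.entries)):
            raise ValueError("m_best must lie in [1, number of candidates]")

    def top(self, m: int | None = None) -> list[tuple[clf.TrainedClassifier, float]]:
        m = self.m_best if m is None else m
        return self.entries[: min(m, len(self.entries))]


@dataclass
class FusionWeights:
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega <= 0) or not np.isclose(self.omega.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")


def softmax_weights(vas: np.ndarray) -> FusionWeights:
    """omega_i = exp(VA_i) / sum_j exp(VA_j); invariant to a common
    shift of all VAs."""
    vas = np.asarray(vas, dtype=float)
    if vas.size == 0:
        raise ValueError("need at least one validation accuracy")
    e = np.exp(vas - vas.max())
    return FusionWeights(e / e.sum())


def order_classifiers(
    X: np.ndarray,
    y: np.ndarray,
    pair_id: str = "",
    algorithms: tuple[str, ...] = clf.ALGORITHMS,
    n_val_folds: int = 5,
    seed: int = 0,
    rls_lambdas: tuple[float, ...] | None = None,
) -> OrderedClassifierList:
    """Train and rank the candidate algorithms on one problem's features.

    Each algorithm's VA is its mean accuracy over seeded stratified
    ``n_val_folds``-fold CV on (X, y); the same estimate later supplies
    the RWA weights.  After scoring, each algorithm is refitted on the
    full (X, y).  Ties keep the canonical algorithm order
    (LPGM, SVM, FLDA, LR, RLS).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = ordered_labels(y)
    lut = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lut[v] for v in y])
    counts = np.bincount(y_idx)
    if counts.min() < n_val_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot run "
            f"{n_val_folds}-fold stratified validation")
    skf = StratifiedKFold(n_splits=n_val_folds, shuffle=True,
                          random_state=derive_seed(seed, "odcs-cv", pair_id))
    folds = list(skf.split(X, y_idx))

    rls_cfg = clf.RLSConfig(rls_lambdas) if rls_lambdas is not None else None
    scored: list[tuple[clf.TrainedClassifier, float]] = []
    for algo in algorithms:
        algo_seed = derive_seed(seed, "odcs-algo", pair_id, algo)
        accs = []
        for tr, va in folds:
            model = clf.train(algo, X[tr], y[tr], seed=algo_seed,
                              rls_config=rls_cfg)
            accs.append(float(np.mean(model.predict(X[va]) == y[va])))
        va_mean = float(np.mean(accs))
        final = clf.train(algo, X, y, seed=algo_seed, rls_config=rls_cfg)
        final.validation_accuracy = va_mean
        scored.append((final, va_mean))
    # stable sort keeps canonical order on ties
    scored.sort(key=lambda t: -t[1])
    return OrderedClassifierList(pair_id=pair_id, entries=scored)


def rwa_fuse(prob_vectors: list[np.ndarray], vas: list[float]) -> np.ndarray:
    """Reliability weighted average of posterior vectors.

    All vectors must be over the same class set in the same order; the
    output is their convex combination with softmax-of-VA weights, hence
    itself on the simplex.
    """
    if len(prob_vectors) == 0:
        raise ValueError("need at least one classifier to fuse")
    P = np.asarray(prob_vectors, dtype=float)
    if P.ndim != 2:
        raise ValueError("probability vectors must share one length")
    w = softmax_weights(np.asarray(vas)).omega
    if len(w) != len(P):
        raise ValueError("one VA per probability vector required")
    return w @ P


def node_posterior(
    ordered: OrderedClassifierList, x: np.ndarray, m_best: int | None = None
) -> dict[str, float]:
    """Fused posterior of one node for one sample, as {class: prob}."""
    entries = ordered.top(m_best)
    classes = entries[0][0].classes
    probs = [model.predict_proba(np.atleast_2d(x))[0] for model, _ in entries]
    vas = [va for _, va in entries]
    fused = rwa_fuse(probs, vas)
    return dict(zip(classes, fused))


def odcs_classify(
    scheme: DecompositionScheme,
    ordered_lists: dict[str, OrderedClassifierList],
    features: dict[str, np.ndarray],
    m_best: int = 1,
) -> tuple[str, dict]:
    """Classify one sample with per-node RWA fusion of the top-m
    candidates, then the scheme's routing.

    ``features`` maps problem_id to the sample's feature vector in that
    problem's PSTF space (each node owns its own chain).  ``m_best``
    larger than the number of candidates is clipped.
    """
    node_probs = {}
    for pid in required_problems(scheme):
        if pid not in ordered_lists:
            raise KeyError(f"no ordered classifier list for node {pid!r}")
        m = min(m_best, len(ordered_lists[pid].entries))
        if m < m_best:
            logging.getLogger(__name__).warning(
                "m_best=%d exceeds the %d candidates at node %s; clipped",
                m_best, m, pid)
        node_probs[pid] = node_posterior(ordered_lists[pid], features[pid], m)
    return classify(scheme, node_probs)
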