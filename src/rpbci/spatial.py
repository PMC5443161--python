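"""Fisher-criterion spatial beamformer.

Each epoch is a channels-by-time matrix X (N x T).  Spatial scatter
matrices over the channel dimension,

    S_b = sum_i p_i (M_i - M)(M_i - M)'          (between classes)
    S_w = sum_i sum_k (X_ik - M_i)(X_ik - M_i)'  (within classes, pooled
                                                  raw scatter, no count
                                                  normalisation)

with M_i the per-class mean epoch, M the grand mean and p_i = K_i / K
the empirical class prior, define the Fisher quotient

    J(W) = (W' S_b W) / (W' (S_w + gamma I) W).

The beamformer is the unit-norm leading eigenvector of the generalized
eigenproblem S_b W = lambda (S_w + gamma I) W; gamma >= 0 is a Tikhonov
regularizer that also enforces non-singularity.  Only the first filter
W^(1) is used; its output for an epoch X is the time course y = W' X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import EpochSet, ordered_labels

__all__ = [
    "ClassStatistics",
    "ScatterPair",
    "BeamformerModel",
    "compute_scatter",
    "fit_beamformer",
    "apply_beamformer",
    "associated_pattern",
    "fisher_quotient",
]


@dataclass
class ClassStatistics:
    class_means: dict[str, np.ndarray]   # label -> (N, T)
    grand_mean: np.ndarray               # (N, T)
    class_priors: dict[str, float]
    class_counts: dict[str, int]


@dataclass
class ScatterPair:
    S_b: np.ndarray
    S_w: np.ndarray

    def __post_init__(self) -> None:
        self.S_b = np.asarray(self.S_b, dtype=float)
        self.S_w = np.asarray(self.S_w, dtype=float)
        for name, s in (("S_b", self.S_b), ("S_w", self.S_w)):
            if s.ndim != 2 or s.shape[0] != s.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(s, s.T, atol=1e-8 * max(1.0, np.abs(s).max())):
                raise ValueError(f"{name} must be symmetric")


@dataclass
class BeamformerModel:
    """Fitted spatial filter W^(1) with its regularizer and spectrum."""

    W: np.ndarray
    gamma: float
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if not np.isclose(np.linalg.norm(self.W), 1.0):
            raise ValueError("W must have unit Euclidean norm")


def compute_scatter(
    es: EpochSet, labels: np.ndarray | None = None
) -> tuple[ClassStatistics, ScatterPair]:
    """Spatial between-/within-class scatter over the channel dimension.

    ``labels`` optionally overrides the epoch labels (used by superclass
    decompositions, e.g. movement-vs-idle, where two original classes
    pool into one).
    """
    y = es.labels if labels is None else np.asarray(labels, dtype=object)
    if len(y) != len(es):
        raise ValueError("labels length must match epoch count")
    classes = ordered_labels(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to compute scatter")
    K = len(es)
    n = es.n_channels
    grand = es.data.mean(axis=0)
    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    priors: dict[str, float] = {}
    S_b = np.zeros((n, n))
    S_w = np.zeros((n, n))
    for c in classes:
        mask = y == c
        k_i = int(mask.sum())
        if k_i < 2:
            raise ValueError(f"class {c!r} has {k_i} epoch(s); need >= 2")
        X_c = es.data[mask]
        m_i = X_c.mean(axis=0)
        means[c] = m_i
        counts[c] = k_i
        priors[c] = k_i / K
        d = m_i - grand
        S_b += priors[c] * (d @ d.T)
        r = X_c - m_i  # (K_i, N, T)
        S_w += np.einsum("knt,kmt->nm", r, r)
    S_b = (S_b + S_b.T) / 2
    S_w = (S_w + S_w.T) / 2
    stats = ClassStatistics(means, grand, priors, counts)
    return stats, ScatterPair(S_b=S_b, S_w=S_w)


def fit_beamformer(sp: ScatterPair, gamma: float = 0.0) -> BeamformerModel:
    """Leading generalized eigenvector of (S_w + gamma I)^-1 S_b.

    Solved on the symmetric-definite form via ``scipy.linalg.eigh(S_b,
    S_w + gamma I)`` (Cholesky whitening internally).  The returned W is
    unit-norm with its largest-magnitude entry made positive, so results
    are deterministic up to that convention.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = sp.S_w.shape[0]
    S_w_reg = sp.S_w + gamma * np.eye(n)
    try:
        evals, evecs = linalg.eigh(sp.S_b, S_w_reg)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "S_w + gamma*I is singular; use gamma > 0") from exc
    if not np.all(np.isfinite(evals)):
        raise np.linalg.LinAlgError(
            "generalized eigenproblem diverged; use gamma > 0")
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    w = evecs[:, order[0]]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return BeamformerModel(W=w, gamma=float(gamma), eigenvalues=evals)


def apply_beamformer(X: np.ndarray, model: BeamformerModel) -> np.ndarray:
    """Spatial filter output y = W' X for one epoch or a stack.

    ``X`` may be (N, T) giving (T,), or (K, N, T) giving (K, T).
    """
    X = np.asarray(X, dtype=float)
    n = model.W.shape[0]
    if X.shape[-2] != n:
        raise ValueError(f"expected {n} channels, got {X.shape[-2]}")
    return np.einsum("n,...nt->...t", model.W, X)


def associated_pattern(es: EpochSet, model: BeamformerModel) -> np.ndarray:
    """Forward spatial pattern of a fitted filter, a = C W (unit norm).

    C is the channel covariance of the concatenated epochs.  While the
    filter W weights channels to *extract* the source, the pattern a is
    the source's estimated projection topography, the quantity to
    compare against a planted mixing vector.
    """
    x = es.data.transpose(1, 0, 2).reshape(es.n_channels, -1)
    x = x - x.mean(axis=1, keepdims=True)
    C = x @ x.T / x.shape[1]
    a = C @ model.W
    nrm = np.linalg.norm(a)
    if nrm == 0:
        raise ValueError("degenerate covariance: zero pattern")
    return a / nrm


def fisher_quotient(sp: ScatterPair, w: np.ndarray, gamma: float = 0.0) -> float:
    """J(w) = (w' S_b w) / (w' (S_w + gamma I) w)."""
    w = np.asarray(w, dtype=float)
    denom = w @ (sp.S_w + gamma * np.eye(len(w))) @ w
    return float(w @ sp.S_b @ w / denom)
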