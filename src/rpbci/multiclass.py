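"""Ternary classification strategies: direct MCS and binary decompositions.

Five ways to decide among right movement (R), idle (I) and left
movement (L):

MCS   one ternary classifier on three-class features;
OAO   one-against-one — classifiers R-I, I-L, R-L, combined by the
      Wu-Lin-Weng pairwise-coupling algorithm (second method);
OAA   one-against-all — classifiers R-A, I-A, L-A (target vs. pooled
      rest), label = class with the highest target probability;
DBT   directed binary tree — root idle-vs-movement, then left-vs-right;
DDAG  decision directed acyclic graph — for a class order
      [c1, c2, c3], the root compares c1 vs c3, eliminates the loser,
      and a second node compares the survivor against c2.

Every strategy returns exactly one of {R, I, L} for every input; ties
are broken toward the earlier class in canonical (R, I, L) order.
Binary training sets are balanced by seeded subsampling of the larger
side (without replacement); for OAA the pooled "All" side is first
subsampled class-proportionally so neither constituent class dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import rng_for
from .core import CLASS_ORDER, IDLE, LEFT, RIGHT, EpochSet, ordered_labels

__all__ = [
    "DecompositionScheme",
    "BinaryProblem",
    "PairwiseProbabilities",
    "build_binary_problems",
    "pairwise_couple",
    "classify",
    "required_problems",
    "MOVEMENT",
    "ALL_REST",
]

#: Superclass labels used by DBT ("movement") and OAA ("all others").
MOVEMENT = "M"
ALL_REST = "A"

_DDAG_ORDERS = {
    "RIL": (RIGHT, IDLE, LEFT),
    "ILR": (IDLE, LEFT, RIGHT),
    "RLI": (RIGHT, LEFT, IDLE),
}


@dataclass(frozen=True)
class DecompositionScheme:
    """A ternary strategy: ``kind`` plus, for DDAG, the node order."""

    kind: str  # mcs | oao | oaa | dbt | ddag
    ddag_order: str = "RIL"

    def __post_init__(self) -> None:
        if self.kind not in ("mcs", "oao", "oaa", "dbt", "ddag"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "ddag" and self.ddag_order not in _DDAG_ORDERS:
            raise ValueError(
                f"ddag_order must be one of {sorted(_DDAG_ORDERS)}")

    @property
    def order(self) -> tuple[str, str, str]:
        return _DDAG_ORDERS[self.ddag_order]


@dataclass
class BinaryProblem:
    """One node's training data: an epoch subset plus (possibly
    superclass-pooled) binary labels aligned with it."""

    problem_id: str
    epochs: EpochSet
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=object)
        if len(self.y) != len(self.epochs):
            raise ValueError("y length must match epoch count")

    @property
    def classes(self) -> list[str]:
        return ordered_labels(self.y)


@dataclass
class PairwiseProbabilities:
    """r[i, j] = estimated P(class i | class i or j, x); r + r.T = 1
    off-diagonal.  Row/column order follows ``classes``."""

    r: np.ndarray
    classes: list[str] = field(default_factory=lambda: list(CLASS_ORDER))

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = self.r.shape[0]
        if self.r.shape != (m, m) or m != len(self.classes):
            raise ValueError("r must be square, matching classes")
        off = ~np.eye(m, dtype=bool)
        if np.any(self.r[off] < -1e-9) or np.any(self.r[off] > 1 + 1e-9):
            raise ValueError("entries must lie in [0, 1]")
        s = self.r + self.r.T
        if not np.allclose(s[off], 1.0, atol=1e-6):
            raise ValueError("r_ij + r_ji must equal 1")


def _pair_id(a: str, b: str) -> str:
    rank = {c: i for i, c in enumerate(CLASS_ORDER)}
    a, b = sorted((a, b), key=lambda c: rank[c])
    return f"{a}-{b}"


def required_problems(scheme: DecompositionScheme) -> list[str]:
    """Problem ids the scheme's classify() step needs, in fit order."""
    if scheme.kind == "mcs":
        return ["RIL"]
    if scheme.kind in ("oao", "ddag"):
        return [_pair_id(RIGHT, IDLE), _pair_id(RIGHT, LEFT), _pair_id(IDLE, LEFT)]
    if scheme.kind == "oaa":
        return [f"{c}-{ALL_REST}" for c in CLASS_ORDER]
    # dbt
    return [f"{IDLE}-{MOVEMENT}", _pair_id(RIGHT, LEFT)]


def _subsample(indices: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    if k > len(indices):
        raise ValueError("cannot subsample beyond pool size")
    if k == len(indices):
        return indices
    return np.sort(rng.choice(indices, size=k, replace=False))


def _proportional_subsample(es: EpochSet, pool: list[str], target: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Subsample a multi-class pool to ``target``, keeping class ratios
    (largest-remainder rounding)."""
    idx_per = {c: np.flatnonzero(es.labels == c) for c in pool}
    total = sum(len(v) for v in idx_per.values())
    raw = {c: target * len(idx_per[c]) / total for c in pool}
    take = {c: int(np.floor(raw[c])) for c in pool}
    rem = target - sum(take.values())
    for c in sorted(pool, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)[:rem]:
        take[c] += 1
    out = [_subsample(idx_per[c], take[c], rng) for c in pool]
    return np.sort(np.concatenate(out))


def build_binary_problems(
    scheme: DecompositionScheme, train: EpochSet, seed: int = 0
) -> list[BinaryProblem]:
    """Assemble the (balanced) training set of every node the scheme needs.

    Balancing subsamples the larger side down to the smaller, without
    replacement, using a seed derived per problem so problems are
    independent and reproducible.  For MCS all three classes are
    subsampled to the minimum class count.
    """
    counts = train.class_counts()
    for c in CLASS_ORDER:
        if counts[c] == 0:
            raise ValueError(f"class {c!r} has zero epochs in training data")
    problems: list[BinaryProblem] = []
    for pid in required_problems(scheme):
        rng = rng_for(seed, "balance", pid)
        if pid == "RIL":  # MCS ternary problem
            k = min(counts.values())
            idx = np.sort(np.concatenate(
                [_subsample(np.flatnonzero(train.labels == c), k, rng)
                 for c in CLASS_ORDER]))
            sub = train.subset(idx)
            problems.append(BinaryProblem(pid, sub, sub.labels))
            continue
        a, b = pid.split("-")
        if b == ALL_REST:
            pool = [c for c in CLASS_ORDER if c != a]
            idx_a = np.flatnonzero(train.labels == a)
            n_pool = sum(counts[c] for c in pool)
            k = min(len(idx_a), n_pool)
            idx_a = _subsample(idx_a, k, rng)
            idx_b = _proportional_subsample(train, pool, k, rng)
            idx = np.sort(np.concatenate([idx_a, idx_b]))
            sub = train.subset(idx)
            y = np.where(sub.labels == a, a, ALL_REST)
            problems.append(BinaryProblem(pid, sub, y))
            continue
        if b == MOVEMENT:
            idx_a = np.flatnonzero(train.labels == IDLE)
            idx_m = np.flatnonzero(np.isin(train.labels, [LEFT, RIGHT]))
            k = min(len(idx_a), len(idx_m))
            idx_a = _subsample(idx_a, k, rng)
            if k < len(idx_m):
                idx_m = _proportional_subsample(train, [LEFT, RIGHT], k, rng)
            idx = np.sort(np.concatenate([idx_a, idx_m]))
            sub = train.subset(idx)
            y = np.where(sub.labels == IDLE, IDLE, MOVEMENT)
            problems.append(BinaryProblem(pid, sub, y))
            continue
        # plain class pair
        idx_a = np.flatnonzero(train.labels == a)
        idx_b = np.flatnonzero(train.labels == b)
        k = min(len(idx_a), len(idx_b))
        idx = np.sort(np.concatenate(
            [_subsample(idx_a, k, rng), _subsample(idx_b, k, rng)]))
        sub = train.subset(idx)
        problems.append(BinaryProblem(pid, sub, sub.labels))
    return problems


def pairwise_couple(pp: PairwiseProbabilities) -> np.ndarray:
    """Couple pairwise probabilities into one posterior vector.

    Solves the constrained least-squares problem

        min_p  sum_{i<j} (r_ji p_i - r_ij p_j)^2
        s.t.   sum_i p_i = 1,  p >= 0

    via its KKT linear system (the Wu-Lin-Weng "second method").  Tiny
    negative components from numerically inconsistent inputs are
    clipped and the vector renormalized.
    """
    r = pp.r
    m = r.shape[0]
    if m == 2:
        return np.array([r[0, 1], r[1, 0]])
    Q = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                Q[i, i] = sum(r[j2, i] ** 2 for j2 in range(m) if j2 != i)
            else:
                Q[i, j] = -r[j, i] * r[i, j]
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = Q
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    rhs = np.zeros(m + 1)
    rhs[m] = 1.0
    sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
    p = np.clip(sol[:m], 0.0, None)
    s = p.sum()
    return p / s if s > 0 else np.full(m, 1.0 / m)


def classify(
    scheme: DecompositionScheme,
    node_probs: dict[str, dict[str, float]],
) -> tuple[str, dict]:
    """Route one sample's per-node posteriors to a ternary label.

    Parameters
    ----------
    node_probs : mapping problem_id -> {node class -> probability}
        One entry per problem in :func:`required_problems`.  Each inner
        dict is the (fused) posterior of that node's classifier for the
        sample being classified.

    Returns
    -------
    (label, diagnostics) where diagnostics records the route taken and
    every intermediate probability.
    """
    for pid in required_problems(scheme):
        if pid not in node_probs:
            raise KeyError(f"missing node model/probabilities for {pid!r}")
    diag: dict = {"scheme": scheme.kind, "probs": node_probs}

    if scheme.kind == "mcs":
        p = node_probs["RIL"]
        label = _argmax_canonical(p)
        return label, diag

    if scheme.kind == "oao":
        classes = list(CLASS_ORDER)
        r = np.full((3, 3), 0.5)
        for i, a in enumerate(classes):
            for j, b in enumerate(classes):
                if i < j:
                    pr = node_probs[_pair_id(a, b)]
                    r[i, j] = pr[a]
                    r[j, i] = pr[b]
        p = pairwise_couple(PairwiseProbabilities(r, classes))
        diag["coupled"] = dict(zip(classes, p))
        label = classes[int(np.argmax(p))]
        return label, diag

    if scheme.kind == "oaa":
        targets = {c: node_probs[f"{c}-{ALL_REST}"][c] for c in CLASS_ORDER}
        diag["target_probs"] = targets
        label = _argmax_canonical(targets)
        return label, diag

    if scheme.kind == "dbt":
        root = node_probs[f"{IDLE}-{MOVEMENT}"]
        route = [f"{IDLE}-{MOVEMENT}"]
        if root[IDLE] >= root[MOVEMENT]:
            diag["route"] = route
            return IDLE, diag
        leaf = node_probs[_pair_id(RIGHT, LEFT)]
        route.append(_pair_id(RIGHT, LEFT))
        diag["route"] = route
        return _argmax_canonical(leaf), diag

    # ddag
    c1, c2, c3 = scheme.order
    root_pid = _pair_id(c1, c3)
    root = node_probs[root_pid]
    survivor = _argmax_canonical({c1: root[c1], c3: root[c3]})
    next_pid = _pair_id(survivor, c2)
    leaf = node_probs[next_pid]
    label = _argmax_canonical({survivor: leaf[survivor], c2: leaf[c2]})
    diag["route"] = [root_pid, next_pid]
    return label, diag


def _argmax_canonical(probs: dict[str, float]) -> str:
    """Highest-probability class; ties go to the earlier class in
    canonical (R, I, L) order (superclass labels last)."""
    order = ordered_labels(probs.keys())
    vals = np.array([probs[c] for c in order])
    return order[int(np.argmax(vals))]
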