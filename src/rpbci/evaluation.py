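"""Cohen's kappa, confusion-matrix bookkeeping, and the outer protocol.

The protocol mirrors a per-participant evaluation with limited trials:
the trial list is split into 10 equal, disjoint, contiguous chunks; each
fold trains every stage (PSTF per node, classifiers, optionally the
ODCS ordering) on 9 chunks and predicts the untouched 10th.  Chunking
is at the *trial* level so a trial's idle and movement epochs always
share a chunk.  Test epochs are never subsampled: the test set keeps
its natural ~2:1:1 idle:left:right imbalance, which is why agreement is
scored by Cohen's kappa

    kappa = (N * sum_i h_ii - sum_i Tr_i * Tc_i)
            / (N^2 - sum_i Tr_i * Tc_i)

(h the confusion matrix with rows = true class, Tr/Tc its marginals)
rather than by raw accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifiers as clf
from ._utils import derive_seed, rng_for
from .core import CLASS_ORDER, EpochSet, ordered_labels
from .multiclass import DecompositionScheme, build_binary_problems, classify
from .odcs import node_posterior, order_classifiers
from .pstf import PSTFGrid, fit_pstf, transform

__all__ = [
    "ConfusionMatrix",
    "FoldPlan",
    "ResultTable",
    "LeakageError",
    "cohen_kappa",
    "make_folds",
    "validate_fold_plan",
    "run_protocol",
]


class LeakageError(RuntimeError):
    """A test trial appeared inside a training structure."""


@dataclass
class ConfusionMatrix:
    """Integer count matrix; rows = correct class, columns = predicted.

    Class order defaults to canonical (R, I, L).
    """

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        m = len(self.classes)
        if self.counts.shape != (m, m):
            raise ValueError(f"counts must be {m}x{m}")
        if np.any(self.counts < 0) or not np.all(self.counts == self.counts.astype(int)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         classes: tuple[str, ...] = CLASS_ORDER) -> "ConfusionMatrix":
        lut = {c: i for i, c in enumerate(classes)}
        h = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            h[lut[t], lut[p]] += 1
        return cls(h, classes)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def accuracy(self) -> float:
        """Overall fraction correct, sum_i h_ii / N."""
        return float(np.trace(self.counts) / self.n)

    def per_class_accuracy(self) -> dict[str, float]:
        """Diagonal count over row marginal, per class (recall)."""
        tr = self.row_marginals
        return {c: float(self.counts[i, i] / tr[i]) if tr[i] else float("nan")
                for i, c in enumerate(self.classes)}

    def kappa(self) -> float:
        return cohen_kappa(self)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class order mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement from a confusion matrix.

    Equivalent to 1 - (1 - P_o) / (1 - P_e) with observed agreement
    P_o = sum h_ii / N and chance agreement P_e = sum Tr_i Tc_i / N^2.
    """
    h = cm.counts
    N = cm.n
    if N == 0:
        raise ValueError("empty confusion matrix")
    tr = cm.row_marginals.astype(np.int64)
    tc = cm.col_marginals.astype(np.int64)
    if np.count_nonzero(tr) < 2 and np.count_nonzero(tc) < 2:
        raise ValueError("kappa needs at least two classes with nonzero marginals")
    chance = int(tr @ tc)
    denom = N * N - chance
    if denom == 0:
        raise ValueError("degenerate matrix: N^2 equals the chance term")
    return float((N * int(np.trace(h)) - chance) / denom)


@dataclass
class FoldPlan:
    """Trial-level chunk assignment for the outer protocol."""

    trial_order: np.ndarray        # unique trial ids, evaluation order
    chunk_of: np.ndarray           # chunk index per entry of trial_order
    n_chunks: int = 10

    def __post_init__(self) -> None:
        self.trial_order = np.asarray(self.trial_order, dtype=int)
        self.chunk_of = np.asarray(self.chunk_of, dtype=int)
        if len(self.trial_order) != len(self.chunk_of):
            raise ValueError("chunk assignment must cover every trial")

    def fold(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(train trial ids, test trial ids) for fold ``k``."""
        test = self.trial_order[self.chunk_of == k]
        train = self.trial_order[self.chunk_of != k]
        return train, test

    def folds(self):
        return [self.fold(k) for k in range(self.n_chunks)]


def make_folds(es: EpochSet, seed: int = 0, n_chunks: int = 10,
               shuffle: bool = False) -> FoldPlan:
    """Split trials into ``n_chunks`` disjoint chunks of equal size (+/-1).

    Chunks are contiguous in chronological trial order by default
    (conservative under slow signal drift); ``shuffle`` permutes trials
    first with the given seed.  Fully determined by its arguments.
    """
    trials = pd.unique(np.asarray(es.trial_indices))
    if len(trials) < n_chunks:
        raise ValueError(f"{len(trials)} trials < {n_chunks} chunks")
    if shuffle:
        trials = rng_for(seed, "fold-shuffle").permutation(trials)
    chunk_of = np.concatenate([
        np.full(len(part), k)
        for k, part in enumerate(np.array_split(np.arange(len(trials)), n_chunks))
    ])
    return FoldPlan(trial_order=trials, chunk_of=chunk_of, n_chunks=n_chunks)


def validate_fold_plan(plan: FoldPlan) -> None:
    """Protocol-integrity audit: chunks disjoint, exhaustive, balanced,
    and no trial shared between any fold's train and test side."""
    if len(np.unique(plan.trial_order)) != len(plan.trial_order):
        raise LeakageError("a trial id appears in more than one chunk")
    sizes = np.bincount(plan.chunk_of, minlength=plan.n_chunks)
    if sizes.max() - sizes.min() > 1:
        raise LeakageError(f"chunk sizes {sizes.tolist()} differ by more than 1")
    if sizes.sum() != len(plan.trial_order):
        raise LeakageError("chunk assignment does not cover all trials")
    for k in range(plan.n_chunks):
        train, test = plan.fold(k)
        if np.intersect1d(train, test).size:
            raise LeakageError(f"fold {k}: train and test share trials")


@dataclass
class ResultTable:
    """Per-fold results plus pooled aggregates."""

    frame: pd.DataFrame
    pooled: ConfusionMatrix
    method: str
    participant_id: str = "P1"

    def mean_kappa(self) -> float:
        """The headline statistic: mean of the per-fold kappas."""
        return float(self.frame["kappa"].mean())

    def sd_kappa(self) -> float:
        return float(self.frame["kappa"].std(ddof=1))

    def pooled_kappa(self) -> float:
        """Kappa of the element-wise sum of fold confusions (may differ
        from the mean of fold kappas; the mean is the headline)."""
        return self.pooled.kappa()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "participant": self.participant_id,
            "method": self.method,
            "mean_kappa": self.mean_kappa(),
            "sd_kappa": self.sd_kappa(),
            "pooled_kappa": self.pooled_kappa(),
            "mean_accuracy": float(self.frame["accuracy"].mean()),
        }])


_CONF_COLS = [f"h_{t}{p}" for t in CLASS_ORDER for p in CLASS_ORDER]


def run_protocol(
    es: EpochSet,
    scheme: DecompositionScheme,
    seed: int = 0,
    algorithm: str = "FLDA",
    use_odcs: bool = False,
    m_best: int = 3,
    algorithms: tuple[str, ...] = clf.ALGORITHMS,
    grid: PSTFGrid | None = None,
    n_chunks: int = 10,
    n_inner_folds: int = 5,
    shuffle_chunks: bool = False,
    plan: FoldPlan | None = None,
    log: list | None = None,
) -> ResultTable:
    """Run the full outer cross-validation protocol on one participant.

    Per fold: balanced binary problems are built from the training
    chunks; each problem gets its own PSTF (grid-searched by inner CV)
    and classifier(s); the untouched test chunk is predicted with no
    subsampling; the fold's confusion matrix and kappa are recorded.

    ``use_odcs`` ranks all candidate ``algorithms`` per node and fuses
    the top ``m_best`` by RWA; otherwise the single ``algorithm`` is
    used everywhere.  A ``plan`` may be supplied (it is audited first —
    a corrupted plan aborts the run).  ``log``, if a list, receives one
    dict per fold with the selected PSTF hyperparameters and, for ODCS,
    the per-node algorithm ordering.
    """
    grid = grid or PSTFGrid.reduced()
    if plan is None:
        plan = make_folds(es, seed=seed, n_chunks=n_chunks, shuffle=shuffle_chunks)
    validate_fold_plan(plan)
    if set(np.asarray(es.trial_indices)) != set(plan.trial_order.tolist()):
        raise LeakageError("fold plan does not match the dataset's trials")
    present = ordered_labels(es.labels)
    if scheme.kind == "mcs" and len(present) < 3:
        raise ValueError("the ternary MCS needs all three classes present")

    rows = []
    pooled = ConfusionMatrix(np.zeros((3, 3), dtype=int))
    for k in range(plan.n_chunks):
        train_trials, test_trials = plan.fold(k)
        if np.intersect1d(train_trials, test_trials).size:
            raise LeakageError(f"fold {k}: corrupted plan")
        tr_mask = np.isin(es.trial_indices, train_trials)
        te_mask = np.isin(es.trial_indices, test_trials)
        train_es = es.subset(np.flatnonzero(tr_mask))
        test_es = es.subset(np.flatnonzero(te_mask))

        fold_seed = derive_seed(seed, "fold", k)
        problems = build_binary_problems(scheme, train_es, seed=fold_seed)
        fold_log: dict = {"fold": k, "pstf": {}, "ordering": {}}

        node_models = {}
        search_clf = "FLDA" if use_odcs else algorithm
        for pb in problems:
            pm = fit_pstf(pb.epochs, grid=grid, classifier_id=search_clf,
                          n_inner_folds=n_inner_folds,
                          seed=derive_seed(fold_seed, "pstf", pb.problem_id),
                          labels=pb.y)
            feats = transform(pm, pb.epochs)
            fold_log["pstf"][pb.problem_id] = {
                "low_pass_hz": pm.filter_spec.low_pass_hz,
                "high_pass_hz": pm.filter_spec.high_pass_hz,
                "gamma": pm.beamformer.gamma,
                "window": pm.window,
                "cv_score": pm.cv_score,
            }
            if use_odcs:
                ordered = order_classifiers(
                    feats, pb.y, pair_id=pb.problem_id, algorithms=algorithms,
                    n_val_folds=n_inner_folds,
                    seed=derive_seed(fold_seed, "odcs", pb.problem_id))
                fold_log["ordering"][pb.problem_id] = [
                    (m.algorithm_id, va) for m, va in ordered.entries]
                node_models[pb.problem_id] = ("odcs", pm, ordered)
            else:
                model = clf.train(
                    algorithm, feats, pb.y,
                    seed=derive_seed(fold_seed, "clf", pb.problem_id))
                node_models[pb.problem_id] = ("single", pm, model)

        # --- predict the untouched test chunk ---------------------------
        test_feats = {pid: transform(nm[1], test_es)
                      for pid, nm in node_models.items()}
        y_pred = []
        for i in range(len(test_es)):
            node_probs = {}
            for pid, (kind_, pm, head) in node_models.items():
                x = test_feats[pid][i]
                if kind_ == "odcs":
                    m = min(m_best, len(head.entries))
                    node_probs[pid] = node_posterior(head, x, m)
                else:
                    p = head.predict_proba(x[None, :])[0]
                    node_probs[pid] = dict(zip(head.classes, p))
            label, _ = classify(scheme, node_probs)
            y_pred.append(label)

        cmat = ConfusionMatrix.from_predictions(test_es.labels, y_pred)
        pooled = pooled + cmat
        row = {"participant": es.participant_id, "method": _method_name(
                   scheme, algorithm, use_odcs, m_best),
               "fold": k, "kappa": cmat.kappa(), "accuracy": cmat.accuracy()}
        row.update({col: int(v) for col, v in
                    zip(_CONF_COLS, cmat.counts.ravel())})
        rows.append(row)
        if log is not None:
            fold_log["kappa"] = row["kappa"]
            log.append(fold_log)

    frame = pd.DataFrame(rows)
    return ResultTable(frame=frame, pooled=pooled,
                       method=_method_name(scheme, algorithm, use_odcs, m_best),
                       participant_id=es.participant_id)


def _method_name(scheme: DecompositionScheme, algorithm: str,
                 use_odcs: bool, m_best: int) -> str:
    base = scheme.kind
    if scheme.kind == "ddag":
        base = f"ddag[{scheme.ddag_order}]"
    if use_odcs:
        return f"odcs{m_best}-{base}"
    return f"{base}-{algorithm}"
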