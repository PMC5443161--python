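"""PSTF: the full spatio-temporal feature-extraction chain.

Chain per epoch: zero-phase band filtering → EOG regression →
Fisher-criterion beamformer (channels → one virtual channel) →
averaging over consecutive non-overlapping windows (T samples → T'
features, T' << T).

The band cut-offs (LPB/HPB), beamformer regularizer gamma and window
size are data-dependent: :func:`fit_pstf` searches their Cartesian grid
exhaustively, scoring every combination by stratified inner
cross-validation with the same classification algorithm that will later
consume the features, and keeps the combination with the highest mean
validation accuracy.  The default candidate grid is

    LPB in {1..7} Hz, HPB in {none, 0.1, 0.3, 0.5} Hz,
    gamma in {0, 1, 10, 1e3, 1e4, 1e5, 1e6}, window in {5, 10, 25},

588 combinations.  Ties break deterministically toward lower LPB, then
no high-pass / lower HPB, then lower gamma, then larger window.  The
EOG regression is fitted once on the training set handed in and frozen
across the grid (filtering and the regression subtraction are both
linear operators, so their order does not change the output).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from ._utils import derive_seed
from .core import EpochSet, ordered_labels
from .preprocess import (EOGModel, FilterSpec, apply_eog_regression,
                         bandpass_filter, fit_eog_regression)
from .spatial import BeamformerModel, apply_beamformer, compute_scatter, fit_beamformer

__all__ = [
    "PSTFGrid",
    "PSTFModel",
    "window_average",
    "fit_pstf",
    "fitted_pattern",
    "transform",
]


@dataclass(frozen=True)
class PSTFGrid:
    """Candidate hyperparameter sets for the PSTF grid search."""

    low_pass_candidates: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7)
    high_pass_candidates: tuple[float | None, ...] = (None, 0.1, 0.3, 0.5)
    gamma_candidates: tuple[float, ...] = (0, 1, 10, 1e3, 1e4, 1e5, 1e6)
    window_candidates: tuple[int, ...] = (5, 10, 25)

    def __post_init__(self) -> None:
        for name in ("low_pass_candidates", "high_pass_candidates",
                     "gamma_candidates", "window_candidates"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    def __len__(self) -> int:
        return (len(self.low_pass_candidates) * len(self.high_pass_candidates)
                * len(self.gamma_candidates) * len(self.window_candidates))

    def combinations(self):
        """Enumerate in tie-break priority order: LPB ascending, HPB
        none-first then ascending, gamma ascending, window DEscending."""
        lp = sorted(self.low_pass_candidates)
        hp = sorted(self.high_pass_candidates,
                    key=lambda h: (h is not None, h if h is not None else 0.0))
        gm = sorted(self.gamma_candidates)
        wd = sorted(self.window_candidates, reverse=True)
        return itertools.product(lp, hp, gm, wd)

    @classmethod
    def reduced(cls) -> "PSTFGrid":
        """A small grid for examples / protocol runs at desk scale."""
        return cls(low_pass_candidates=(1, 3),
                   high_pass_candidates=(None,),
                   gamma_candidates=(1e3, 1e5),
                   window_candidates=(5, 10))


@dataclass
class PSTFModel:
    """A fitted chain: frozen filter spec, EOG weights, beamformer, window."""

    filter_spec: FilterSpec
    eog_model: EOGModel | None
    beamformer: BeamformerModel
    window: int
    cv_score: float
    fs: float
    n_channels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.cv_score <= 1.0):
            raise ValueError("cv_score must lie in [0, 1]")


def window_average(y: np.ndarray, w: int) -> np.ndarray:
    """Mean over consecutive non-overlapping windows of ``w`` samples.

    Works on the last axis; trailing samples that do not fill a window
    are dropped (floor rule), so T' = floor(T / w).
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    y = np.asarray(y, dtype=float)
    T = y.shape[-1]
    if w > T:
        raise ValueError(f"window {w} exceeds signal length {T}")
    T_out = T // w
    trimmed = y[..., : T_out * w]
    return trimmed.reshape(*y.shape[:-1], T_out, w).mean(axis=-1)


def _inner_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Stratified, seeded fold assignment — a pure function of
    (labels, n_folds, seed)."""
    classes = ordered_labels(labels)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < n_folds:
        raise ValueError(
            f"class counts {counts} too small for {n_folds}-fold "
            "stratified inner CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    lut = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lut[v] for v in labels])
    return list(skf.split(np.zeros(len(labels)), y_idx))


def fit_pstf(
    train: EpochSet,
    grid: PSTFGrid | None = None,
    classifier_id: str = "FLDA",
    n_inner_folds: int = 5,
    seed: int = 0,
    labels: np.ndarray | None = None,
    score_table: list | None = None,
) -> PSTFModel:
    """Exhaustive grid search over the PSTF hyperparameters.

    ``labels`` optionally overrides the epoch labels (binary problems
    with superclass pooling).  If ``score_table`` is a list it receives
    one ``(lp, hp, gamma, window, mean_accuracy)`` row per combination,
    for audit.  Combinations whose beamformer fails numerically (e.g.
    gamma = 0 on singular within-class scatter) score 0 rather than
    aborting the search.
    """
    grid = grid or PSTFGrid()
    y = train.labels if labels is None else np.asarray(labels, dtype=object)
    if len(y) != len(train):
        raise ValueError("labels length must match epoch count")
    folds = _inner_folds(y, n_inner_folds, derive_seed(seed, "inner-cv"))

    # EOG regression: fitted once on the training set, frozen across the
    # grid (linear, commutes with the linear band filters).
    eog_model = None
    base = train
    if train.eog is not None:
        eog_model = fit_eog_regression(train)
        base = apply_eog_regression(train, eog_model)

    best = None  # (score, lp, hp, gamma, window)
    clf_seed = derive_seed(seed, "grid-clf")
    prev_filter = None
    filtered = None
    for lp, hp, gamma, w in grid.combinations():
        if (lp, hp) != prev_filter:
            filtered = bandpass_filter(base, FilterSpec(lp, hp))
            prev_filter = (lp, hp)
            fold_scatter = {}  # fold index -> ScatterPair (gamma-independent)
        accs = []
        ok = True
        for fi, (tr_idx, va_idx) in enumerate(folds):
            if fi not in fold_scatter:
                _, fold_scatter[fi] = compute_scatter(
                    filtered.subset(tr_idx), labels=y[tr_idx])
            try:
                bf = fit_beamformer(fold_scatter[fi], gamma=gamma)
            except np.linalg.LinAlgError:
                ok = False
                break
            feats_tr = window_average(
                apply_beamformer(filtered.data[tr_idx], bf), w)
            feats_va = window_average(
                apply_beamformer(filtered.data[va_idx], bf), w)
            model = clf.train(classifier_id, feats_tr, y[tr_idx], seed=clf_seed)
            pred = model.predict(feats_va)
            accs.append(float(np.mean(pred == y[va_idx])))
        score = float(np.mean(accs)) if ok and accs else 0.0
        if score_table is not None:
            score_table.append((lp, hp, gamma, w, score))
        if best is None or score > best[0]:
            best = (score, lp, hp, gamma, w)

    score, lp, hp, gamma, w = best
    spec = FilterSpec(lp, hp)
    final = bandpass_filter(base, spec)
    _, sp = compute_scatter(final, labels=y)
    try:
        bf = fit_beamformer(sp, gamma=gamma)
    except np.linalg.LinAlgError:
        # winner scored with per-fold scatter but full-train scatter is
        # singular at gamma=0: fall back to a minimal jitter
        bf = fit_beamformer(sp, gamma=1e-8 * max(np.trace(sp.S_w), 1.0))
    return PSTFModel(filter_spec=spec, eog_model=eog_model, beamformer=bf,
                     window=int(w), cv_score=score, fs=train.fs,
                     n_channels=train.n_channels)


def fitted_pattern(model: PSTFModel, es: EpochSet) -> np.ndarray:
    """Forward spatial pattern of the fitted beamformer on ``es``.

    The epochs are passed through the frozen EOG regression and band
    filter first, so the pattern reflects the signal subspace the
    beamformer actually operates on (raw-data covariance would be
    dominated by unremoved artifacts).
    """
    from .spatial import associated_pattern

    base = es
    if model.eog_model is not None and es.eog is not None:
        base = apply_eog_regression(es, model.eog_model)
    cleaned = bandpass_filter(base, model.filter_spec)
    return associated_pattern(cleaned, model.beamformer)


def transform(model: PSTFModel, es: EpochSet) -> np.ndarray:
    """Apply a frozen PSTF chain; returns the (K, T') feature table."""
    if es.fs != model.fs:
        raise ValueError(
            f"sampling rate {es.fs} differs from fitted rate {model.fs}")
    if es.n_channels != model.n_channels:
        raise ValueError(
            f"channel count {es.n_channels} differs from fitted "
            f"{model.n_channels}")
    base = es
    if model.eog_model is not None:
        if es.eog is None:
            raise ValueError("model was fitted with EOG regression but the "
                             "input carries no EOG")
        base = apply_eog_regression(es, model.eog_model)
    filtered = bandpass_filter(base, model.filter_spec)
    y = apply_beamformer(filtered.data, model.beamformer)
    return window_average(y, model.window)
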