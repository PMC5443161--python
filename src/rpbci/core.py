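"""Core domain types, trial screening, and epoch extraction.

The experimental unit is a *trial*: continuous multichannel EEG (plus
parallel EOG) spanning a rest period, an auditory cue, and a
self-initiated key press.  Each valid trial yields two fixed-length
epochs: a 500 ms *idle* segment immediately preceding the cue, and a
500 ms *movement* segment ending 130 ms before the key press (the
window that contains the late, lateralized readiness potential).

Class labels are ``"L"`` (left movement), ``"R"`` (right movement) and
``"I"`` (idle).  The canonical class order used for deterministic
tie-breaking throughout the package is (R, I, L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "CLASS_ORDER",
    "IDLE",
    "LEFT",
    "RIGHT",
    "TrialRecord",
    "Epoch",
    "EpochSet",
    "ScreeningReport",
    "EpochExtractionError",
    "ordered_labels",
    "screen_trials",
    "extract_epochs",
    "time_to_sample",
]

RIGHT = "R"
IDLE = "I"
LEFT = "L"
#: Canonical class order; earlier classes win deterministic ties.
CLASS_ORDER = (RIGHT, IDLE, LEFT)

#: Epoch duration in seconds (idle and movement).
EPOCH_DURATION_S = 0.5
#: Movement epoch ends this long before the key press.
PRE_PRESS_GAP_S = 0.130
#: A press within this interval after the cue is a reactive response.
REACTIVE_WINDOW_S = 2.0


class EpochExtractionError(ValueError):
    """A trial lacks the samples required for epoch extraction."""


def ordered_labels(y) -> list[str]:
    """Distinct labels in canonical (R, I, L) order; superclass labels
    (anything outside {R, I, L}) follow, sorted alphabetically."""
    present = set(y)
    out = [c for c in CLASS_ORDER if c in present]
    out += sorted(present - set(CLASS_ORDER))
    return out


def time_to_sample(t: float, fs: float) -> int:
    """Convert seconds to a 0-based sample index.

    Uses round-half-away-from-zero on ``t * fs`` so window lengths are
    stable across floating-point representations of the same instant.
    """
    x = t * fs
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class TrialRecord:
    """One recorded trial of continuous EEG/EOG.

    Parameters
    ----------
    continuous_eeg : ndarray, shape (n_channels, n_samples)
    continuous_eog : ndarray, shape (n_eog, n_samples)
    fs : float
        Sampling rate in Hz.
    cue_time : float
        Auditory-cue onset, seconds from trial start.
    press_times : sequence of float
        Key-press times, seconds from trial start.  May be empty or
        contain multiple presses (both rejected by screening).
    cue_side : str
        ``"L"`` or ``"R"`` — the side announced by the cue.
    """

    continuous_eeg: np.ndarray
    continuous_eog: np.ndarray
    fs: float
    cue_time: float
    press_times: Sequence[float]
    cue_side: str
    participant_id: str = "P1"
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.continuous_eeg = np.asarray(self.continuous_eeg, dtype=float)
        self.continuous_eog = np.asarray(self.continuous_eog, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.cue_time < 0:
            raise ValueError("cue_time must be >= 0")
        dur = self.continuous_eeg.shape[1] / self.fs
        for p in self.press_times:
            if not (0 <= p <= dur):
                raise ValueError(f"press time {p} outside trial duration {dur}")
        if self.cue_side not in (LEFT, RIGHT):
            raise ValueError(f"cue_side must be 'L' or 'R', got {self.cue_side!r}")

    @property
    def duration(self) -> float:
        return self.continuous_eeg.shape[1] / self.fs


@dataclass
class Epoch:
    """A fixed-length labeled segment of multichannel EEG."""

    data: np.ndarray  # (n_channels, n_samples)
    label: str
    participant_id: str = "P1"
    trial_index: int = 0
    eog: np.ndarray | None = None  # (n_eog, n_samples), time-locked

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.label not in CLASS_ORDER:
            raise ValueError(f"label must be one of {CLASS_ORDER}, got {self.label!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")


@dataclass
class EpochSet:
    """An ordered collection of equal-length epochs with shared metadata.

    Internally array-backed for efficiency: ``data`` is (K, N, T),
    ``labels`` is a length-K object array over {"L","R","I"}, and
    ``eog`` (optional) is (K, n_eog, T).
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    fs: float
    eog: np.ndarray | None = None
    trial_indices: np.ndarray | None = None
    participant_id: str = "P1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (K, N, T)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match epoch count")
        bad = set(self.labels) - set(CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown labels {bad}; expected subset of {CLASS_ORDER}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal n_channels")
        if self.eog is not None:
            self.eog = np.asarray(self.eog, dtype=float)
            if self.eog.shape[0] != self.data.shape[0] or self.eog.shape[2] != self.data.shape[2]:
                raise ValueError("eog must be (K, n_eog, T) matching data")
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.data.shape[0])
        else:
            self.trial_indices = np.asarray(self.trial_indices, dtype=int)
            if len(self.trial_indices) != self.data.shape[0]:
                raise ValueError("trial_indices length must match epoch count")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, k: int) -> Epoch:
        return Epoch(
            data=self.data[k],
            label=self.labels[k],
            participant_id=self.participant_id,
            trial_index=int(self.trial_indices[k]),
            eog=None if self.eog is None else self.eog[k],
        )

    def __iter__(self) -> Iterator[Epoch]:
        for k in range(len(self)):
            yield self[k]

    @property
    def epochs(self) -> list[Epoch]:
        return list(self)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> dict[str, int]:
        """Epoch count per class, in canonical (R, I, L) order."""
        return {c: int(np.sum(self.labels == c)) for c in CLASS_ORDER}

    def subset(self, indices: Sequence[int] | np.ndarray) -> "EpochSet":
        idx = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            channel_names=list(self.channel_names),
            fs=self.fs,
            eog=None if self.eog is None else self.eog[idx],
            trial_indices=self.trial_indices[idx],
            participant_id=self.participant_id,
        )

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  eog: np.ndarray | None = None) -> "EpochSet":
        """Copy of this set with replaced signal arrays (labels/order kept)."""
        return EpochSet(
            data=data,
            labels=self.labels,
            channel_names=list(self.channel_names),
            fs=self.fs if fs is None else fs,
            eog=eog if eog is not None else self.eog,
            trial_indices=self.trial_indices,
            participant_id=self.participant_id,
        )

    @classmethod
    def from_epochs(cls, epochs: Sequence[Epoch], channel_names: list[str],
                    fs: float, participant_id: str = "P1") -> "EpochSet":
        if len(epochs) == 0:
            n = len(channel_names)
            return cls(np.empty((0, n, 0)), np.empty(0, dtype=object),
                       channel_names, fs, participant_id=participant_id)
        lengths = {e.data.shape[1] for e in epochs}
        if len(lengths) != 1:
            raise ValueError("all epochs must share one length")
        data = np.stack([e.data for e in epochs])
        labels = np.array([e.label for e in epochs], dtype=object)
        tidx = np.array([e.trial_index for e in epochs])
        eog = None
        if all(e.eog is not None for e in epochs):
            eog = np.stack([e.eog for e in epochs])
        return cls(data, labels, channel_names, fs, eog=eog,
                   trial_indices=tidx, participant_id=participant_id)


@dataclass
class ScreeningReport:
    """Bookkeeping of the trial screening pass."""

    n_input: int
    n_rejected_reactive: int
    n_rejected_multipress: int
    kept_indices: list[int] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + self.n_rejected_reactive + self.n_rejected_multipress:
            raise ValueError("screening counts inconsistent")


def screen_trials(trials: Sequence[TrialRecord]) -> tuple[list[TrialRecord], ScreeningReport]:
    """Discard reactive and multi-press trials.

    A kept trial has exactly one key press, occurring at least 2 s after
    the auditory cue (otherwise the press is reactive rather than
    self-initiated).  A press before the cue also counts as reactive.
    Trials with zero or multiple presses are rejected as multi-press /
    no-press.
    """
    kept: list[TrialRecord] = []
    kept_idx: list[int] = []
    n_reactive = 0
    n_multi = 0
    for i, tr in enumerate(trials):
        if len(tr.press_times) != 1:
            n_multi += 1
            continue
        latency = tr.press_times[0] - tr.cue_time
        if latency < REACTIVE_WINDOW_S:
            n_reactive += 1
            continue
        kept.append(tr)
        kept_idx.append(i)
    report = ScreeningReport(
        n_input=len(trials),
        n_rejected_reactive=n_reactive,
        n_rejected_multipress=n_multi,
        kept_indices=kept_idx,
    )
    return kept, report


def extract_epochs(trial: TrialRecord, fs_target: float | None = None) -> tuple[Epoch, Epoch]:
    """Cut the idle and movement epochs out of a screened trial.

    idle     = the 500 ms window ending at the cue, labeled ``"I"``;
    movement = the 500 ms window ending 130 ms before the (single) key
               press, labeled by ``cue_side``.

    Windows are half-open ``[start, end)`` in samples.  EOG segments are
    cut with identical windows and attached to each epoch.  ``fs_target``
    must equal the trial's sampling rate (resampling is a separate,
    explicit preprocessing step); it defaults to ``trial.fs``.
    """
    fs = trial.fs
    if fs_target is not None and fs_target != fs:
        raise ValueError(
            "extract_epochs does not resample; downsample after extraction")
    if len(trial.press_times) != 1:
        raise EpochExtractionError(
            f"trial {trial.trial_index}: expected exactly one press, "
            f"got {len(trial.press_times)} (screen first)")
    n = time_to_sample(EPOCH_DURATION_S, fs)
    press = trial.press_times[0]

    idle_end = time_to_sample(trial.cue_time, fs)
    idle_start = idle_end - n
    mov_start = time_to_sample(press - PRE_PRESS_GAP_S - EPOCH_DURATION_S, fs)
    mov_end = mov_start + n

    n_total = trial.continuous_eeg.shape[1]
    if idle_start < 0:
        raise EpochExtractionError(
            f"trial {trial.trial_index}: only {idle_end} samples before cue, "
            f"need {n}")
    if mov_start < 0 or mov_end > n_total:
        raise EpochExtractionError(
            f"trial {trial.trial_index}: movement window [{mov_start}, {mov_end}) "
            f"outside trial of {n_total} samples")

    def cut(arr: np.ndarray, a: int, b: int) -> np.ndarray:
        return np.array(arr[:, a:b])

    idle = Epoch(
        data=cut(trial.continuous_eeg, idle_start, idle_end),
        label=IDLE,
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        eog=cut(trial.continuous_eog, idle_start, idle_end),
    )
    movement = Epoch(
        data=cut(trial.continuous_eeg, mov_start, mov_end),
        label=trial.cue_side,
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        eog=cut(trial.continuous_eog, mov_start, mov_end),
    )
    return idle, movement
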