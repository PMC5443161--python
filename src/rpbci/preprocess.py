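"""Pre-processing: zero-phase band filtering, decimation, EOG regression.

Readiness potentials live below a few Hz, so the working chain is
downsample (anti-aliased) → EOG artifact regression → cascaded
low-/high-pass Butterworth filtering applied forward-backward for zero
phase shift.  All three operators are linear and epoch-order preserving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EpochSet

__all__ = [
    "FilterSpec",
    "EOGModel",
    "bandpass_filter",
    "downsample",
    "fit_eog_regression",
    "apply_eog_regression",
]

#: Butterworth order used for each pass (low and high separately).
BUTTER_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """Cut-offs of the cascaded low-pass / optional high-pass pair."""

    low_pass_hz: float
    high_pass_hz: float | None = None
    order: int = BUTTER_ORDER

    def __post_init__(self) -> None:
        if self.low_pass_hz <= 0:
            raise ValueError("low_pass_hz must be positive")
        if self.high_pass_hz is not None and not (0 < self.high_pass_hz < self.low_pass_hz):
            raise ValueError("need 0 < high_pass_hz < low_pass_hz")


@dataclass
class EOGModel:
    """Least-squares regression weights of EEG on EOG.

    ``coefficients`` has shape (n_eog, n_channels); the cleaned EEG is
    ``EEG - coefficients.T @ EOG`` sample-wise.
    """

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("EOG coefficients must be finite")


def _filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    # reflect-pad one epoch length: epochs are short (~50 samples)
    # relative to the filter transient at sub-Hz cut-offs.
    padlen = max(data.shape[-1] - 1, 1)
    return signal.sosfiltfilt(sos, data, axis=-1, padtype="even", padlen=padlen)


def bandpass_filter(es: EpochSet, spec: FilterSpec) -> EpochSet:
    """Apply the zero-phase low-pass (and optional high-pass) cascade.

    Filters are designed as separate Butterworth low- and high-pass
    stages and each is run forward-backward (squaring its magnitude
    response, zeroing its phase).
    """
    nyq = es.fs / 2.0
    if spec.low_pass_hz >= nyq:
        raise ValueError(f"low-pass cut-off {spec.low_pass_hz} >= Nyquist {nyq}")
    if spec.high_pass_hz is not None and spec.high_pass_hz >= nyq:
        raise ValueError(f"high-pass cut-off {spec.high_pass_hz} >= Nyquist {nyq}")

    out = es.data
    sos_lp = signal.butter(spec.order, spec.low_pass_hz, btype="low",
                           fs=es.fs, output="sos")
    out = _filtfilt(sos_lp, out)
    if spec.high_pass_hz is not None:
        sos_hp = signal.butter(spec.order, spec.high_pass_hz, btype="high",
                               fs=es.fs, output="sos")
        out = _filtfilt(sos_hp, out)
    return es.with_data(out)


def downsample(es: EpochSet, fs_target: float) -> EpochSet:
    """Anti-aliased integer-factor decimation to ``fs_target``.

    EOG channels are decimated with the same filter so they stay
    time-locked to the EEG.
    """
    if fs_target == es.fs:
        return es.with_data(es.data.copy(),
                            eog=None if es.eog is None else es.eog.copy())
    q = es.fs / fs_target
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValueError(
            f"fs {es.fs} not an integer multiple of target {fs_target}")
    q = int(round(q))
    data = signal.decimate(es.data, q, axis=-1, ftype="iir", zero_phase=True)
    eog = None
    if es.eog is not None:
        eog = signal.decimate(es.eog, q, axis=-1, ftype="iir", zero_phase=True)
    return es.with_data(data, fs=fs_target, eog=eog)


def fit_eog_regression(es: EpochSet, ridge: float = 0.0) -> EOGModel:
    """Fit EEG-on-EOG regression over all concatenated training samples.

    Solves ``b = Cov(EOG)^-1 Cov(EOG, EEG)`` on demeaned, concatenated
    epochs.  A singular EOG covariance (e.g. a constant channel) is
    jittered with ``1e-10 * trace * I`` instead of failing, so grid
    searches over degenerate synthetic inputs proceed.
    """
    if es.eog is None:
        raise ValueError("EpochSet carries no EOG channels")
    if len(es) < 2:
        raise ValueError("need at least 2 epochs to fit EOG regression")
    # (n_eog, K*T) and (N, K*T)
    eog = np.concatenate(list(es.eog), axis=1)
    eeg = np.concatenate(list(es.data), axis=1)
    eog = eog - eog.mean(axis=1, keepdims=True)
    eeg = eeg - eeg.mean(axis=1, keepdims=True)
    n = eog.shape[1]
    c_oo = eog @ eog.T / n
    c_oe = eog @ eeg.T / n
    jitter = ridge if ridge > 0 else 0.0
    tr = np.trace(c_oo)
    try:
        b = np.linalg.solve(c_oo + jitter * np.eye(len(c_oo)), c_oe)
    except np.linalg.LinAlgError:
        b = None
    if b is None or not np.all(np.isfinite(b)):
        b = np.linalg.solve(c_oo + (jitter + 1e-10 * max(tr, 1.0)) * np.eye(len(c_oo)), c_oe)
    return EOGModel(coefficients=b)


def apply_eog_regression(es: EpochSet, model: EOGModel) -> EpochSet:
    """Subtract the EOG-predicted component: ``EEG - b.T @ EOG``."""
    if es.eog is None:
        raise ValueError("EpochSet carries no EOG channels")
    b = model.coefficients
    if b.shape != (es.eog.shape[1], es.n_channels):
        raise ValueError(
            f"coefficient shape {b.shape} does not match "
            f"({es.eog.shape[1]}, {es.n_channels})")
    # einsum over epochs: data[k] - b.T @ eog[k]
    cleaned = es.data - np.einsum("on,koT->knT", b, es.eog)
    return es.with_data(cleaned)
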