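"""Synthetic readiness-potential EEG with known ground truth.

Emulates the structure of a self-initiated key-press experiment: per
trial, continuous 34-channel EEG plus 4 EOG channels at 1 kHz; an
auditory cue; a self-paced key press with latency drawn from a
truncated normal (mean 4.76 s, SD 1.98 s, minimum 2 s for valid
trials); an idle interval before the cue and a slow negative ramp
(the readiness potential) starting 1.5 s before the press, larger over
the motor channels contralateral to the moving hand (C1/C3/CP1/CP3 for
right-hand, C2/C4/CP2/CP4 for left-hand presses).  Background activity
is 1/f-shaped ("pink") noise per channel plus a shared common-mode
term, an 8-12 Hz alpha component, and blink artifacts generated on the
EOG channels and mixed into the EEG through a known frontal-weighted
matrix — so the EOG regression step has an exactly planted target.

A configurable fraction of trials deliberately violates the screening
rules (reactive presses within 2 s of the cue; double presses).

Default amplitudes put the planted classes in a clearly separable
regime; they are a synthetic calibration, not an estimate of real
single-trial RP signal-to-noise (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._utils import rng_for
from .core import LEFT, RIGHT, EpochSet, TrialRecord, extract_epochs, screen_trials

__all__ = [
    "CHANNEL_NAMES_34",
    "SimConfig",
    "GroundTruth",
    "simulate_dataset",
    "make_separability_suite",
    "epochs_from_trials",
]

#: Standard 10-10 style montage of the 34 EEG channels.
CHANNEL_NAMES_34 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "C1", "Cz", "C2", "C4", "T8",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2", "POz",
]

#: Motor-area channels carrying the planted patterns.
LEFT_HEMI_MOTOR = ("C1", "C3", "CP1", "CP3")   # contralateral to RIGHT hand
RIGHT_HEMI_MOTOR = ("C2", "C4", "CP2", "CP4")  # contralateral to LEFT hand

_FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
_FRONTOCENTRAL = ("FC5", "FC1", "FC2", "FC6")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; amplitudes in microvolts."""

    n_channels: int = 34
    n_eog: int = 4
    fs_acquire: float = 1000.0
    n_trials_per_side: int = 200
    rp_amplitude: float = 10.0
    lateralization_ratio: float = 2.0
    noise_pink: float = 1.8
    noise_alpha: float = 0.8
    eog_artifact_rate: float = 0.3     # expected blinks per trial
    eog_blink_amplitude: float = 100.0
    p_reactive: float = 0.015
    p_multipress: float = 0.01
    press_latency_mean: float = 4.76
    press_latency_sd: float = 1.98
    two_slope: bool = False            # early/late RP refinement
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rp_amplitude", "noise_pink", "noise_alpha",
                     "eog_artifact_rate", "eog_blink_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_reactive", "p_multipress"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lateralization_ratio < 1:
            raise ValueError("lateralization_ratio must be >= 1")
        if self.n_channels != len(CHANNEL_NAMES_34):
            raise ValueError("only the 34-channel montage is supported")


@dataclass
class GroundTruth:
    """What was planted: spatial patterns, RP time course, EOG mixing."""

    pattern_left: np.ndarray    # unit vector, channels; left-hand trials
    pattern_right: np.ndarray   # unit vector, channels; right-hand trials
    rp_waveform: np.ndarray     # s(t) sampled at fs over [-1.5, +0.3] s re press
    rp_times: np.ndarray
    true_eog_mixing: np.ndarray  # (n_eog, n_channels)
    channel_names: list[str] = field(default_factory=lambda: list(CHANNEL_NAMES_34))


def _planted_pattern(contra: tuple[str, ...], ipsi: tuple[str, ...],
                     ratio: float) -> np.ndarray:
    p = np.zeros(len(CHANNEL_NAMES_34))
    for name in contra:
        p[CHANNEL_NAMES_34.index(name)] = ratio
    for name in ipsi:
        p[CHANNEL_NAMES_34.index(name)] = 1.0
    return p / np.linalg.norm(p)


def _default_eog_mixing(n_eog: int) -> np.ndarray:
    """Frontal-weighted blink propagation, fixed and known."""
    weights = np.full(len(CHANNEL_NAMES_34), 0.01)
    for name in _FRONTAL:
        weights[CHANNEL_NAMES_34.index(name)] = 0.25
    for name in _FRONTOCENTRAL:
        weights[CHANNEL_NAMES_34.index(name)] = 0.08
    # each EOG channel projects the same topography with its own gain
    gains = np.array([1.0, 0.9, -0.7, -0.6])[:n_eog]
    return gains[:, None] * weights[None, :]


def _rp_course(t: np.ndarray, press: float, two_slope: bool) -> np.ndarray:
    """Unit-depth negative ramp from press-1.5 s to the press, linear
    recovery over 0.3 s after it."""
    s = np.zeros_like(t)
    ramp = (t >= press - 1.5) & (t < press)
    if two_slope:
        early = ramp & (t < press - 0.5)
        late = ramp & (t >= press - 0.5)
        s[early] = -0.3 * (t[early] - (press - 1.5)) / 1.0
        s[late] = -0.3 - 0.7 * (t[late] - (press - 0.5)) / 0.5
    else:
        s[ramp] = -(t[ramp] - (press - 1.5)) / 1.5
    rec = (t >= press) & (t < press + 0.3)
    s[rec] = -1.0 + (t[rec] - press) / 0.3
    return s


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                fs: float) -> np.ndarray:
    """1/f-amplitude shaped white noise, unit variance per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    nz = f > 0
    shaping[nz] = 1.0 / np.maximum(f[nz], 0.1)
    spec *= shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _alpha_noise(rng: np.random.Generator, shape: tuple[int, int],
                 fs: float) -> np.ndarray:
    n_ch, n = shape
    t = np.arange(n) / fs
    f = rng.uniform(8.0, 12.0, size=n_ch)[:, None]
    phase = rng.uniform(0, 2 * np.pi, size=n_ch)[:, None]
    # sin has RMS 1/sqrt(2); scale to unit RMS
    return math.sqrt(2.0) * np.sin(2 * np.pi * f * t[None, :] + phase)


def _blink_train(rng: np.random.Generator, n: int, fs: float,
                 rate: float, amplitude: float) -> np.ndarray:
    """Sum of 300 ms raised-cosine deflections at Poisson times."""
    out = np.zeros(n)
    n_blinks = rng.poisson(rate)
    width = int(round(0.3 * fs))
    template = amplitude * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    for _ in range(n_blinks):
        start = rng.integers(0, max(n - width, 1))
        seg = min(width, n - start)
        out[start:start + seg] += template[:seg] * rng.uniform(0.8, 1.2)
    return out


def simulate_dataset(cfg: SimConfig) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate the full trial list plus its ground truth.

    Fully determined by ``cfg.seed``.  Trial sides are a seeded
    permutation of ``n_trials_per_side`` left and right cues; reactive
    and double-press trials are planted at rates ``p_reactive`` and
    ``p_multipress`` (they later fail :func:`~rpbci.core.screen_trials`
    on purpose).
    """
    fs = cfg.fs_acquire
    pattern_right = _planted_pattern(LEFT_HEMI_MOTOR, RIGHT_HEMI_MOTOR,
                                     cfg.lateralization_ratio)
    pattern_left = _planted_pattern(RIGHT_HEMI_MOTOR, LEFT_HEMI_MOTOR,
                                    cfg.lateralization_ratio)
    mixing = _default_eog_mixing(cfg.n_eog)

    rng_struct = rng_for(cfg.seed, "structure")
    sides = np.array([LEFT] * cfg.n_trials_per_side + [RIGHT] * cfg.n_trials_per_side)
    sides = rng_struct.permutation(sides)
    u = rng_struct.uniform(size=len(sides))
    kinds = np.where(u < cfg.p_reactive, "reactive",
                     np.where(u < cfg.p_reactive + cfg.p_multipress,
                              "multipress", "valid"))

    # truncated-normal latency for valid presses (>= 2 s after cue)
    a = (2.0 - cfg.press_latency_mean) / cfg.press_latency_sd
    trials: list[TrialRecord] = []
    for i, (side, kind) in enumerate(zip(sides, kinds)):
        rng = rng_for(cfg.seed, "trial", i)
        cue = rng.uniform(1.0, 2.0)
        if kind == "reactive":
            latency = rng.uniform(0.3, 1.9)
        else:
            latency = stats.truncnorm.rvs(
                a, np.inf, loc=cfg.press_latency_mean,
                scale=cfg.press_latency_sd, random_state=rng)
        press = cue + latency
        presses = [press]
        tail = 0.4
        if kind == "multipress":
            presses.append(press + rng.uniform(0.5, 1.0))
            tail += presses[1] - press
        n = int(round((press + tail) * fs))
        t = np.arange(n) / fs

        pattern = pattern_right if side == RIGHT else pattern_left
        s = _rp_course(t, press, cfg.two_slope)
        eeg = cfg.rp_amplitude * pattern[:, None] * s[None, :]

        if cfg.noise_pink > 0:
            indep = _pink_noise(rng, (cfg.n_channels, n), fs)
            common = _pink_noise(rng, (1, n), fs)
            eeg += cfg.noise_pink * (indep + 0.5 * common)
        if cfg.noise_alpha > 0:
            eeg += cfg.noise_alpha * _alpha_noise(rng, (cfg.n_channels, n), fs)

        blink = _blink_train(rng, n, fs, cfg.eog_artifact_rate,
                             cfg.eog_blink_amplitude)
        gains = np.array([1.0, 0.9, -0.7, -0.6])[: cfg.n_eog]
        eog = gains[:, None] * blink[None, :]
        if cfg.noise_pink > 0:
            eog = eog + 2.0 * _pink_noise(rng, (cfg.n_eog, n), fs)
        # mix artifact into EEG through the known matrix
        eeg += mixing.T @ eog

        trials.append(TrialRecord(
            continuous_eeg=eeg, continuous_eog=eog, fs=fs, cue_time=cue,
            press_times=presses, cue_side=side, participant_id="SIM",
            trial_index=i))

    rp_times = np.arange(int(round(1.8 * fs))) / fs - 1.5
    gt = GroundTruth(
        pattern_left=pattern_left, pattern_right=pattern_right,
        rp_waveform=_rp_course(rp_times, 0.0, cfg.two_slope),
        rp_times=rp_times, true_eog_mixing=mixing)
    return trials, gt


def make_separability_suite(
    levels: list[float], base: SimConfig | None = None
) -> list[tuple[SimConfig, list[TrialRecord], GroundTruth]]:
    """Datasets sharing one ground truth with only the noise rescaled.

    ``levels`` are ascending signal-to-noise multipliers relative to the
    base configuration: level 0 removes the signal entirely (pure
    noise), ``inf`` removes the noise, and a finite level x divides the
    base noise amplitudes by x.
    """
    if sorted(levels) != list(levels):
        raise ValueError("levels must be sorted ascending")
    base = base or SimConfig()
    out = []
    for lv in levels:
        if lv == 0:
            cfg = replace(base, rp_amplitude=0.0)
        elif math.isinf(lv):
            cfg = replace(base, noise_pink=0.0, noise_alpha=0.0)
        else:
            cfg = replace(base, noise_pink=base.noise_pink / lv,
                          noise_alpha=base.noise_alpha / lv)
        trials, gt = simulate_dataset(cfg)
        out.append((cfg, trials, gt))
    return out


def epochs_from_trials(trials: list[TrialRecord],
                       channel_names: list[str] | None = None) -> EpochSet:
    """Screen, extract, and stack epochs from raw trials.

    Each surviving trial contributes its idle and movement epoch, in
    trial order (idle first), so downstream trial-level chunking keeps
    the pair together.
    """
    kept, _ = screen_trials(trials)
    if not kept:
        raise ValueError("no trials survived screening")
    epochs = []
    for tr in kept:
        idle, mov = extract_epochs(tr)
        epochs.extend([idle, mov])
    names = channel_names or list(CHANNEL_NAMES_34)
    return EpochSet.from_epochs(
        epochs, channel_names=names, fs=kept[0].fs,
        participant_id=kept[0].participant_id)
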