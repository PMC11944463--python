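"""Synthetic epoched-EEG generation.

Generates 64-channel scalp epochs (plus optional EOG channels) with the
statistical structure the decoding analysis assumes: 1/f ("pink") background
noise plus white sensor noise, optional spatial correlation across channels,
and class-discriminative topographic effects injected in configurable time
windows for configurable (group, morph-condition) cells.

Emotion classes differ only through their injected topographies; emotionally
averaged stimuli never receive a class effect, so under zero effect amplitude
the data distribution is exchangeable across emotion labels by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import AVERAGE, EMOTIONS, Subject

#: BioSemi 64-channel layout, extended 10-20 names (A1..B32).
SCALP_64 = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: External electrodes used for the horizontal/vertical electrooculogram.
EOG_LABELS = ("EXG1", "EXG2", "EXG3", "EXG4")


@dataclass
class EpochedEEG:
    """Trials x channels x timepoints voltage array with metadata.

    ``data`` is in microvolts; ``times`` is in milliseconds relative to
    stimulus onset, strictly increasing with uniform spacing
    ``1000 / sampling_rate``.  ``trial_meta`` carries one row per trial with
    at least ``emotion``, ``morph``, ``stimulus_ref`` and ``block`` columns.
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    channel_labels: list[str]
    trial_meta: pd.DataFrame
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.times) != n_t:
            raise ValueError("times length must match the timepoint axis")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length must match the channel axis")
        if len(self.trial_meta) != n_tr:
            raise ValueError("trial_meta length must match the trial axis")
        if n_t > 1:
            dt = np.diff(self.times)
            step = 1000.0 / self.sampling_rate
            if not np.allclose(dt, step, rtol=0, atol=1e-6):
                raise ValueError("times must be uniform at 1000/sampling_rate ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self, data: np.ndarray | None = None,
             times: np.ndarray | None = None,
             sampling_rate: float | None = None,
             channel_labels: list[str] | None = None) -> "EpochedEEG":
        """Shallow-config copy with optionally replaced array fields."""
        return EpochedEEG(
            data=self.data.copy() if data is None else data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            times=self.times.copy() if times is None else times,
            channel_labels=list(self.channel_labels) if channel_labels is None else list(channel_labels),
            trial_meta=self.trial_meta.copy(),
            subject_id=self.subject_id,
            group=self.group,
        )


@dataclass(frozen=True)
class EffectSpec:
    """A class-discriminative topographic effect for one (group, morph) cell.

    Within ``window_ms`` the effect adds ``amplitude * topography(emotion)``
    (in microvolts) to every applicable trial, modulated by a rectangular
    temporal envelope with optional raised-cosine on/off ramps of
    ``ramp_ms`` milliseconds.
    """

    group: str
    morph: str
    window_ms: tuple[float, float] = (500.0, 900.0)
    amplitude: float = 1.0
    topography_seed: int = 7
    ramp_ms: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Noise and effect parameters governing synthesis.

    Defaults emulate the study design: 64 scalp channels sampled at 500 Hz
    over a -200..1000 ms epoch, pink (1/f) background plus white sensor
    noise at realistic microvolt scale, and late (500-900 ms) emotion
    effects for the musician group in the full and F0 morph conditions only.
    """

    n_channels: int = 64
    acquisition_rate: float = 500.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    white_noise_sd: float = 2.0
    pink_noise_sd: float = 5.0
    pink_alpha: float = 1.0
    channel_mixing: float = 0.3
    effects: tuple[EffectSpec, ...] = (
        EffectSpec(group="musician", morph="full"),
        EffectSpec(group="musician", morph="f0"),
        EffectSpec(group="musician", morph="timbre", amplitude=0.0),
    )
    class_topography_separation: float = 1.0
    include_eog: bool = True
    emotions: tuple[str, ...] = EMOTIONS
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.white_noise_sd < 0 or self.pink_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.channel_mixing <= 1.0:
            raise ValueError("channel_mixing must lie in [0, 1]")
        t0, t1 = self.epoch_window
        if t1 <= t0:
            raise ValueError("epoch_window must be increasing")
        for eff in self.effects:
            if eff.amplitude < 0:
                raise ValueError("effect amplitudes must be >= 0")
            w0, w1 = eff.window_ms
            if w0 < t0 or w1 > t1 or w1 <= w0:
                raise ValueError(
                    f"effect window {eff.window_ms} outside epoch {self.epoch_window}"
                )


def epoch_times(config: SimulationConfig) -> np.ndarray:
    """Left-aligned sample grid over the epoch window, half-open on the right."""
    t0, t1 = config.epoch_window
    step = 1000.0 / config.acquisition_rate
    n = int(round((t1 - t0) / step))
    return t0 + step * np.arange(n)


def class_topographies(config: SimulationConfig,
                       topography_seed: int) -> dict[str, np.ndarray]:
    """Per-emotion scalp topographies.

    Drawn once per (seed, emotion) from a seeded standard normal over the
    scalp channels and scaled by ``class_topography_separation``; no
    anatomical claim is made, only exchangeable, reproducible separation
    between classes.
    """
    topo = {}
    for idx, emotion in enumerate(config.emotions):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(topography_seed), idx])
        )
        topo[emotion] = (
            rng.standard_normal(config.n_channels)
            * config.class_topography_separation
        )
    return topo


def _pink_filter(n_times: int, alpha: float) -> np.ndarray:
    """rfft-domain amplitude filter with 1/f^(alpha/2) roll-off, zero DC."""
    freqs = np.fft.rfftfreq(n_times)
    h = np.zeros_like(freqs)
    h[1:] = freqs[1:] ** (-alpha / 2.0)
    return h


def _noise(rng: np.random.Generator, shape: tuple[int, ...],
           config: SimulationConfig) -> np.ndarray:
    """Pink + white noise along the last axis, per-trace sd as configured."""
    n_t = shape[-1]
    out = np.zeros(shape)
    if config.pink_noise_sd > 0:
        white = rng.standard_normal(shape)
        shaped = np.fft.irfft(
            np.fft.rfft(white, axis=-1) * _pink_filter(n_t, config.pink_alpha),
            n=n_t, axis=-1,
        )
        sd = shaped.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += shaped * (config.pink_noise_sd / sd)
    if config.white_noise_sd > 0:
        out += config.white_noise_sd * rng.standard_normal(shape)
    return out


def _envelope(times: np.ndarray, window: tuple[float, float],
              ramp_ms: float) -> np.ndarray:
    """Rectangular envelope on [w0, w1), optionally with raised-cosine ramps."""
    w0, w1 = window
    env = ((times >= w0) & (times < w1)).astype(float)
    if ramp_ms > 0:
        rise = (times >= w0) & (times < w0 + ramp_ms)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - w0) / ramp_ms))
        fall = (times >= w1 - ramp_ms) & (times < w1)
        env[fall] = 0.5 * (1 - np.cos(np.pi * (w1 - times[fall]) / ramp_ms))
    return env


def simulate_subject_eeg(
    trial_table: pd.DataFrame,
    design: pd.DataFrame,
    subject: Subject,
    config: SimulationConfig,
) -> EpochedEEG:
    """Simulate one subject's epoched EEG.

    Each trial is pink + white noise (optionally spatially correlated via
    ``channel_mixing``) plus the sum of all effects applicable to
    (subject.group, trial.morph): ``amplitude * topography(emotion) *
    envelope(t)``.  Emotion-average trials receive no class effect.
    Bit-reproducible from ``(config.master_seed, subject.seed)``.
    """
    config.validate()
    times = epoch_times(config)
    n_t = len(times)
    n_trials = len(trial_table)
    n_scalp = config.n_channels
    n_eog = len(EOG_LABELS) if config.include_eog else 0
    n_ch = n_scalp + n_eog

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.master_seed), int(subject.seed)])
    )

    data = _noise(rng, (n_trials, n_ch, n_t), config)
    c = config.channel_mixing
    if c > 0:
        shared = _noise(rng, (n_trials, 1, n_t), config)
        data = np.sqrt(1.0 - c) * data + np.sqrt(c) * shared

    meta = trial_table.merge(
        design[["stimulus_id", "emotion", "morph", "speaker", "pseudoword"]],
        left_on="stimulus_ref", right_on="stimulus_id", how="left",
    ).drop(columns="stimulus_id")

    for eff in config.effects:
        if eff.group != subject.group or eff.amplitude == 0:
            continue
        env = _envelope(times, eff.window_ms, eff.ramp_ms)
        topo = class_topographies(config, eff.topography_seed)
        applicable = (meta["morph"] == eff.morph) & (meta["emotion"] != AVERAGE)
        for emotion in config.emotions:
            rows = np.flatnonzero(applicable & (meta["emotion"] == emotion))
            if rows.size:
                bump = eff.amplitude * np.outer(topo[emotion], env)
                data[rows, :n_scalp, :] += bump

    labels = list(SCALP_64[:n_scalp])
    if n_scalp > len(SCALP_64):
        labels += [f"CH{i}" for i in range(len(SCALP_64) + 1, n_scalp + 1)]
    labels += list(EOG_LABELS[:n_eog])

    return EpochedEEG(
        data=data,
        sampling_rate=config.acquisition_rate,
        times=times,
        channel_labels=labels,
        trial_meta=meta,
        subject_id=subject.subject_id,
        group=subject.group,
    )


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """The same world with every effect amplitude forced to zero."""
    config = config or SimulationConfig()
    zeroed = tuple(replace(e, amplitude=0.0) for e in config.effects)
    return replace(config, effects=zeroed)
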