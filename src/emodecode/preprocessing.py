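"""Preprocessing chain for epoched (or continuous) EEG.

The chain is deliberately minimal: resample to 250 Hz, average reference,
(segment if continuous), drop the EOG channels, baseline-correct against the
pre-stimulus interval, and anti-alias downsample to 100 Hz.  No frequency
filtering and no artifact or channel rejection are applied anywhere — the
downstream classifier is left to handle noisy epochs and channels.

Resampling detrends each trace first (linear fit), resamples the residual
with a polyphase anti-aliasing filter, and restores the trend evaluated at
the new timepoints, so DC offsets and slow drifts survive the rate change.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import EOG_LABELS, EpochedEEG


@dataclass(frozen=True)
class PreprocessConfig:
    first_resample_rate: float = 250.0
    final_rate: float = 100.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    drop_labels: tuple[str, ...] = EOG_LABELS

    def validate(self) -> None:
        if self.final_rate > self.first_resample_rate:
            raise ValueError("final_rate must be <= first_resample_rate")
        (e0, e1), (b0, b1) = self.epoch_window, self.baseline_window
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline_window must lie within epoch_window")


def _linear_fit(times: np.ndarray, data: np.ndarray):
    """Least-squares line per trace; returns (intercept, slope) broadcastable
    against a time axis."""
    t = np.asarray(times, dtype=np.float64)
    tc = t - t.mean()
    denom = (tc**2).sum()
    mean = data.mean(axis=-1, keepdims=True)
    if denom == 0:
        slope = np.zeros_like(mean)
    else:
        slope = ((data - mean) * tc).sum(axis=-1, keepdims=True) / denom
    intercept = mean - slope * t.mean()
    return intercept, slope


def resample(eeg: EpochedEEG, target_rate: float) -> EpochedEEG:
    """Anti-aliased rational-factor resampling with trend restoration.

    Per epoch and channel the linear trend is removed, the residual is
    resampled with :func:`scipy.signal.resample_poly`, and the trend is
    evaluated on the new time grid and added back.  Output length is
    ``round(n * target / source)``; the time axis is regenerated on the same
    left-aligned window.
    """
    if target_rate > eeg.sampling_rate:
        raise ValueError(
            f"upsampling requested: {target_rate} Hz > {eeg.sampling_rate} Hz"
        )
    if target_rate == eeg.sampling_rate:
        return eeg.copy()

    frac = Fraction(target_rate / eeg.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    n_old = eeg.n_times
    n_new = int(round(n_old * target_rate / eeg.sampling_rate))

    intercept, slope = _linear_fit(eeg.times, eeg.data)
    detrended = eeg.data - (intercept + slope * eeg.times)
    res = signal.resample_poly(detrended, up, down, axis=-1)[..., :n_new]

    new_times = eeg.times[0] + (1000.0 / target_rate) * np.arange(n_new)
    out = res + intercept + slope * new_times
    return eeg.copy(data=out, times=new_times, sampling_rate=target_rate)


def scalp_mask(channel_labels: list[str],
               drop_labels: tuple[str, ...] = EOG_LABELS) -> np.ndarray:
    return np.array([lab not in drop_labels for lab in channel_labels])


def rereference_average(eeg: EpochedEEG,
                        eog_labels: tuple[str, ...] = EOG_LABELS) -> EpochedEEG:
    """Subtract the instantaneous mean across scalp channels from every scalp
    channel (EOG channels are excluded from the mean and left untouched)."""
    mask = scalp_mask(eeg.channel_labels, eog_labels)
    if mask.sum() < 2:
        raise ValueError("average reference needs at least 2 scalp channels")
    data = eeg.data.copy()
    mean = data[:, mask, :].mean(axis=1, keepdims=True)
    data[:, mask, :] -= mean
    return eeg.copy(data=data)


def drop_channels(eeg: EpochedEEG, labels: tuple[str, ...]) -> EpochedEEG:
    keep = np.array([lab not in labels for lab in eeg.channel_labels])
    kept_labels = [lab for lab in eeg.channel_labels if lab not in labels]
    return eeg.copy(data=eeg.data[:, keep, :], channel_labels=kept_labels)


def segment_epochs(
    continuous: np.ndarray,
    sampling_rate: float,
    channel_labels: list[str],
    event_onsets_ms: np.ndarray,
    epoch_window: tuple[float, float] = (-200.0, 1000.0),
    trial_meta: pd.DataFrame | None = None,
) -> EpochedEEG:
    """Cut a channels x samples continuous record into stimulus-locked epochs.

    ``event_onsets_ms`` are onset times from the start of the record; each
    epoch spans ``epoch_window`` relative to its onset on the left-aligned
    grid.  An onset whose window leaves the record raises an error naming
    the trial.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous record must be channels x samples")
    n_ch, n_samp = continuous.shape
    step = 1000.0 / sampling_rate
    w0, w1 = epoch_window
    n_t = int(round((w1 - w0) / step))
    onsets = np.atleast_1d(np.asarray(event_onsets_ms, dtype=np.float64))

    epochs = np.empty((len(onsets), n_ch, n_t))
    for i, onset in enumerate(onsets):
        start = int(round((onset + w0) / step))
        if start < 0 or start + n_t > n_samp:
            raise ValueError(
                f"trial {i}: epoch [{onset + w0:g}, {onset + w1:g}] ms falls "
                f"outside the {n_samp / sampling_rate * 1000:g} ms record"
            )
        epochs[i] = continuous[:, start:start + n_t]

    if trial_meta is None:
        trial_meta = pd.DataFrame(index=range(len(onsets)))
    times = w0 + step * np.arange(n_t)
    return EpochedEEG(
        data=epochs, sampling_rate=sampling_rate, times=times,
        channel_labels=list(channel_labels), trial_meta=trial_meta,
    )


def baseline_correct(eeg: EpochedEEG,
                     baseline_window: tuple[float, float] = (-200.0, 0.0)
                     ) -> EpochedEEG:
    """Subtract the per-trial, per-channel mean over the baseline interval
    (half-open ``[b0, b1)``) from the whole epoch."""
    b0, b1 = baseline_window
    mask = (eeg.times >= b0) & (eeg.times < b1)
    if not mask.any():
        raise ValueError(
            f"baseline window [{b0:g}, {b1:g}) ms contains no samples"
        )
    base = eeg.data[..., mask].mean(axis=-1, keepdims=True)
    return eeg.copy(data=eeg.data - base)


def preprocess(eeg: EpochedEEG,
               config: PreprocessConfig = PreprocessConfig()) -> EpochedEEG:
    """The full chain on epoched input.

    resample to ``first_resample_rate`` -> average reference -> drop EOG
    channels -> baseline correction -> resample to ``final_rate``.  With the
    default synthetic subject (68 channels at 500 Hz, -200..1000 ms) the
    output is 64 channels x 120 timepoints per trial at 100 Hz, the decoding
    grid -200, -190, ..., 990 ms.  No filtering, no artifact rejection.
    """
    config.validate()
    if eeg.sampling_rate < config.first_resample_rate:
        raise ValueError(
            f"input rate {eeg.sampling_rate} Hz below first resample rate "
            f"{config.first_resample_rate} Hz"
        )
    stages = [
        ("resample_first", lambda x: resample(x, config.first_resample_rate)),
        ("average_reference",
         lambda x: rereference_average(x, config.drop_labels)),
        ("drop_eog", lambda x: drop_channels(x, config.drop_labels)),
        ("baseline", lambda x: baseline_correct(x, config.baseline_window)),
        ("resample_final", lambda x: resample(x, config.final_rate)),
    ]
    out = eeg
    for name, stage in stages:
        try:
            out = stage(out)
        except ValueError as err:
            raise ValueError(f"preprocessing stage {name!r}: {err}") from err
    return out
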