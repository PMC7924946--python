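"""Epoching, detrending, re-referencing and re-time-locking of EEG.

Epochs are cut trigger-locked (the trigger starts the thermode ramp),
centred and linearly detrended per channel.  The band-pass contract
(1-100 Hz Butterworth order 4, zero-phase) applies to the continuous
recording *before* epoching to keep filter edge artifacts outside the
epochs.  Re-referencing to the common average reconstructs the original
reference channel (FCz) as a data channel.  Re-locking moves t = 0 from
the trigger to the cue onset (cue-locked) or to the moment the thermode
reaches its target temperature (stimulus-locked); the ramp delay is
(T_target - 33 degC) / (40 degC/s), i.e. 225/325/375 ms for 42/46/48
degC.  Shifts are applied as nearest-sample rolls of the time axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .design import ConditionCell, TEMPERATURES

__all__ = [
    "EpochSet",
    "ramp_shift",
    "bandpass",
    "epoch_and_detrend",
    "rereference_common_average",
    "relock",
    "apply_keep_mask",
    "BASELINE_TEMPERATURE",
    "RAMP_RATE",
    "DEFAULT_EPOCH_WINDOW",
]

logger = logging.getLogger(__name__)

BASELINE_TEMPERATURE = 33.0  # degC, thermode resting temperature
RAMP_RATE = 40.0  # degC/s heating gradient
#: trigger-locked epoch extent (s): 3410 ms before to 2505 ms after trigger
DEFAULT_EPOCH_WINDOW = (-3.410, 2.505)


@dataclass
class EpochSet:
    """Per-subject epoched EEG: trials x channels x samples.

    ``times`` is the common sample-time axis (s) relative to the lock
    event (``lock`` in {"trigger", "cue", "stimulus"}).  ``conditions``
    holds one :class:`~cuedpain.design.ConditionCell` per trial (``None``
    for trials without a heat condition).  ``cue_onset`` is the per-trial
    cue onset time in *trigger-locked* seconds (negative: cue precedes
    the trigger).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    conditions: list[ConditionCell | None]
    lock: str = "trigger"
    reference: str = "FCz"
    cue_onset: np.ndarray | None = None
    #: accumulated lock shift per trial (s), trigger-locked frame -> current
    lock_shift: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_s = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError("ch_names length does not match data")
        if len(self.conditions) != n_tr:
            raise ValueError("conditions length does not match data")
        if self.times.shape != (n_s,):
            raise ValueError("times length does not match data")
        dt = np.diff(self.times)
        if n_s > 1 and not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
            raise ValueError("time axis must be uniform at 1/sfreq")
        if self.lock_shift is None:
            self.lock_shift = np.zeros(n_tr)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self, **changes) -> "EpochSet":
        out = replace(self, **changes)
        return out


def ramp_shift(stimulus_level: int) -> float:
    """Thermode ramp time (s) from baseline to the level's target temperature."""
    if stimulus_level not in TEMPERATURES:
        raise ValueError(f"unknown stimulus level {stimulus_level!r}")
    return (TEMPERATURES[stimulus_level] - BASELINE_TEMPERATURE) / RAMP_RATE


def bandpass(
    continuous: np.ndarray,
    sfreq: float,
    low: float = 1.0,
    high: float = 100.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a continuous recording."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, continuous, axis=-1)


def epoch_and_detrend(
    continuous: np.ndarray,
    sfreq: float,
    triggers: np.ndarray,
    ch_names: list[str],
    conditions: list[ConditionCell | None] | None = None,
    window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
    cue_onset: np.ndarray | None = None,
    reference: str = "FCz",
) -> EpochSet:
    """Cut trigger-locked epochs; centre and linearly detrend each channel.

    ``triggers`` are event times in seconds.  Triggers whose window falls
    outside the recording are rejected with a logged reason.  The input
    is expected to be band-pass filtered already (see :func:`bandpass`).
    """
    continuous = np.asarray(continuous)
    n_samples = continuous.shape[-1]
    start_off = int(round(window[0] * sfreq))
    n_epoch = int(round((window[1] - window[0]) * sfreq)) + 1
    times = (start_off + np.arange(n_epoch)) / sfreq

    epochs, kept_cond, kept_cue = [], [], []
    conditions = conditions if conditions is not None else [None] * len(triggers)
    cue_arr = np.asarray(cue_onset, float) if cue_onset is not None else None
    for k, t0 in enumerate(np.asarray(triggers, float)):
        i0 = int(round(t0 * sfreq)) + start_off
        i1 = i0 + n_epoch
        if i0 < 0 or i1 > n_samples:
            logger.warning(
                "rejecting trigger %d at %.3f s: window [%d, %d) outside recording of %d samples",
                k, t0, i0, i1, n_samples,
            )
            continue
        epochs.append(continuous[:, i0:i1])
        kept_cond.append(conditions[k])
        kept_cue.append(cue_arr[k] if cue_arr is not None else np.nan)
    if not epochs:
        raise ValueError("no epoch survived: all triggers too close to recording edges")

    data = signal.detrend(np.stack(epochs), axis=-1, type="linear")
    cue_out = None if cue_arr is None else np.array(kept_cue)
    return EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        ch_names=list(ch_names),
        conditions=kept_cond,
        lock="trigger",
        reference=reference,
        cue_onset=cue_out,
    )


def rereference_common_average(epochs: EpochSet, reference_name: str = "FCz") -> EpochSet:
    """Re-reference to the common average, recovering the old reference.

    The original reference channel carries zero potential in its own
    referencing; it is appended as an all-zero channel, then every
    channel gets the mean over all channels (including the recovered
    one) subtracted.  The channel mean is exactly zero afterwards.
    Applying the function to already average-referenced data is a no-op.
    """
    if epochs.reference == "common_average":
        logger.info("data already common-average referenced; no-op")
        return epochs
    n_tr, n_ch, n_s = epochs.data.shape
    zeros = np.zeros((n_tr, 1, n_s), dtype=epochs.data.dtype)
    data = np.concatenate([epochs.data, zeros], axis=1)
    data = data - data.mean(axis=1, keepdims=True)
    return epochs.copy(
        data=data,
        ch_names=list(epochs.ch_names) + [reference_name],
        reference="common_average",
    )


def _trial_shifts(epochs: EpochSet, mode: str) -> np.ndarray:
    """Per-trial lock shift (s) from the current frame to ``mode``'s frame."""
    if mode == "trigger":
        target = np.zeros(epochs.n_trials)
    elif mode == "cue":
        if epochs.cue_onset is None:
            raise ValueError("cue-locked relock requires per-trial cue onsets")
        target = np.asarray(epochs.cue_onset, float)
    elif mode == "stimulus":
        target = np.empty(epochs.n_trials)
        for i, cell in enumerate(epochs.conditions):
            if cell is None:
                raise ValueError(f"trial {i} has no condition; cannot stimulus-lock")
            target[i] = ramp_shift(cell.stimulus_level)
    else:
        raise ValueError(f"unknown lock mode {mode!r}")
    return target - epochs.lock_shift


def relock(epochs: EpochSet, mode: str) -> EpochSet:
    """Move t = 0 to the cue onset, the stimulus plateau, or the trigger.

    Shifts are rounded to the nearest sample.  The common time axis is
    cropped to the range supported by every trial; shifting back restores
    the original time-axis values on that range (exact inverse up to the
    cropping).
    """
    shifts = _trial_shifts(epochs, mode)
    k = np.round(shifts * epochs.sfreq).astype(int)
    n_s = epochs.data.shape[-1]
    # a sample with old index j in trial i gets new index m = j - k_i and
    # new time t_old[j] - k_i/sfreq = t_old[0] + m/sfreq; keep the m-range
    # supported by every trial
    m_lo = -int(k.min())
    m_hi = n_s - 1 - int(k.max())
    if m_hi < m_lo:
        raise ValueError("lock shifts exceed the epoch extent")
    n_out = m_hi - m_lo + 1
    out = np.empty(epochs.data.shape[:2] + (n_out,), dtype=epochs.data.dtype)
    for i in range(epochs.n_trials):
        j0 = m_lo + int(k[i])
        out[i] = epochs.data[i, :, j0 : j0 + n_out]
    times = epochs.times[0] + (m_lo + np.arange(n_out)) / epochs.sfreq
    return epochs.copy(
        data=out,
        times=times,
        lock=mode,
        lock_shift=epochs.lock_shift + k / epochs.sfreq,
    )


def apply_keep_mask(epochs: EpochSet, keep: np.ndarray) -> EpochSet:
    """Drop trials flagged bad by an external (e.g. visual/ICA) screen."""
    keep = np.asarray(keep, bool)
    if keep.shape != (epochs.n_trials,):
        raise ValueError("keep mask length does not match trial count")
    return epochs.copy(
        data=epochs.data[keep],
        conditions=[c for c, k in zip(epochs.conditions, keep) if k],
        cue_onset=None if epochs.cue_onset is None else epochs.cue_onset[keep],
        lock_shift=epochs.lock_shift[keep],
    )
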