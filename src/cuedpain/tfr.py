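"""Sliding-window time-frequency decomposition and z-baseline normalization.

Low frequencies (1-30 Hz, 1 Hz grid) use a single 300 ms Hanning taper;
high frequencies (31-100 Hz, 1 Hz grid) use a 200 ms multitaper window
with +/-15 Hz spectral smoothing (discrete prolate spheroidal tapers,
K = 2*T*W - 1 = 5).  Both slide in 50 ms steps.  The 1 Hz grid is finer
than the windows' native resolution, so segments are zero-padded to a
1 s equivalent length before the FFT.

Baseline normalization is the classical additive model: per subject,
channel and frequency, the mean and standard deviation of the
trial-averaged power over a pre-cue baseline window are estimated, the
mean subtracted from every time point and the difference divided by the
standard deviation.  Default windows: -650..-150 ms cue-locked and
-2950..-2450 ms stimulus-locked.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.fft import rfft
from scipy.signal import windows

from .design import ConditionCell
from .preprocess import EpochSet

__all__ = [
    "TFR",
    "BaselineSpec",
    "tfr_hanning",
    "tfr_multitaper",
    "zbaseline",
    "average_by_condition",
    "LOW_FREQS",
    "HIGH_FREQS",
]

LOW_FREQS = np.arange(1.0, 31.0)
HIGH_FREQS = np.arange(31.0, 101.0)
TIME_STEP = 0.05  # s, spectral estimate spacing


@dataclass
class TFR:
    """Time-frequency power: (trials or conditions) x channels x freqs x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list[str]
    estimator: dict
    baseline_state: str = "raw"  # "raw" (uV^2) or "z"
    conditions: list[ConditionCell | None] | None = None
    cells: list[ConditionCell] | None = None  # set after condition averaging

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if self.power.ndim != 4:
            raise ValueError("power must be 4-D (units x channels x freqs x times)")
        if self.power.shape[1:] != (len(self.ch_names), len(self.freqs), len(self.times)):
            raise ValueError("power shape inconsistent with axes")

    def copy(self, **changes) -> "TFR":
        return replace(self, **changes)

    def crop(self, tmin: float | None = None, tmax: float | None = None,
             fmin: float | None = None, fmax: float | None = None) -> "TFR":
        tol = 1e-9
        tsel = np.ones(len(self.times), bool)
        if tmin is not None:
            tsel &= self.times >= tmin - tol
        if tmax is not None:
            tsel &= self.times <= tmax + tol
        fsel = np.ones(len(self.freqs), bool)
        if fmin is not None:
            fsel &= self.freqs >= fmin - tol
        if fmax is not None:
            fsel &= self.freqs <= fmax + tol
        return self.copy(
            power=self.power[:, :, fsel][:, :, :, tsel],
            freqs=self.freqs[fsel],
            times=self.times[tsel],
        )


def _default_times(epoch_times: np.ndarray, half_window: float, step: float) -> np.ndarray:
    """All step-grid times with full window support inside the epoch."""
    lo = epoch_times[0] + half_window
    hi = epoch_times[-1] - half_window
    t0 = np.ceil(lo / step - 1e-9) * step
    t1 = np.floor(hi / step + 1e-9) * step
    if t1 < t0:
        raise ValueError("epoch too short for the analysis window")
    return np.round(np.arange(t0, t1 + step / 2, step), 9)


def _sliding_power(
    epochs: EpochSet,
    freqs: np.ndarray,
    times: np.ndarray | None,
    window_length: float,
    tapers: np.ndarray,
    step: float,
    pad_seconds: float,
    max_chunk_mb: float = 256.0,
) -> TFR:
    """Tapered sliding-window power, averaged over ``tapers``.

    ``tapers`` has shape (K, n_win).  Output power is the mean over the
    K taper estimates of ``|FFT(segment * taper)|^2``, scaled so that the
    estimate is a power spectral density per taper (the absolute scale
    cancels in all downstream statistics).
    """
    sfreq = epochs.sfreq
    n_win = tapers.shape[1]
    half = window_length / 2.0
    if times is None:
        times = _default_times(epochs.times, half, step)
    times = np.asarray(times, float)
    lo, hi = epochs.times[0], epochs.times[-1]
    bad = (times - half < lo - 1e-9) | (times + half > hi + 1e-9)
    if bad.any():
        raise ValueError(
            f"requested times without full {window_length*1e3:.0f} ms window support: "
            f"{times[bad][:5]}..."
        )

    n_pad = int(round(pad_seconds * sfreq))
    if n_pad < n_win:
        raise ValueError("zero-pad length shorter than the analysis window")
    fft_freqs = np.arange(n_pad // 2 + 1) / pad_seconds
    bins = np.array([int(round(f * pad_seconds)) for f in freqs])
    if np.any(np.abs(fft_freqs[bins] - freqs) > 1e-6):
        raise ValueError("requested frequencies do not lie on the zero-padded FFT grid")
    if freqs.max() > sfreq / 2:
        raise ValueError("requested frequency above Nyquist")

    # segment start index per output time (window centred on the time point)
    centers = np.round((times - epochs.times[0]) * sfreq).astype(int)
    starts = np.clip(centers - n_win // 2, 0, epochs.data.shape[-1] - n_win)
    seg_idx = starts[:, None] + np.arange(n_win)[None, :]

    n_tr, n_ch, _ = epochs.data.shape
    n_t, n_f, n_k = len(times), len(freqs), tapers.shape[0]
    scale = 1.0 / (sfreq * (tapers[0] ** 2).sum())
    power = np.empty((n_tr, n_ch, n_f, n_t), np.float32)
    # chunk trials to bound the (trials*ch, times, pad) workspace
    bytes_per_trial = n_ch * n_t * n_pad * 8
    chunk = max(1, int(max_chunk_mb * 1e6 / max(bytes_per_trial, 1)))
    for a in range(0, n_tr, chunk):
        b = min(a + chunk, n_tr)
        seg = epochs.data[a:b][:, :, seg_idx]  # (tr, ch, t, win)
        acc = np.zeros((b - a, n_ch, n_t, n_f))
        for k in range(n_k):
            spec = rfft(seg * tapers[k], n=n_pad, axis=-1)[..., bins]
            acc += np.abs(spec) ** 2
        power[a:b] = (scale / n_k) * np.transpose(acc, (0, 1, 3, 2))
    return TFR(
        power=power,
        freqs=freqs,
        times=times,
        ch_names=list(epochs.ch_names),
        estimator={
            "window_length": window_length,
            "step": step,
            "n_tapers": n_k,
            "pad_seconds": pad_seconds,
            "lock": epochs.lock,
        },
        conditions=list(epochs.conditions),
    )


def tfr_hanning(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
    window_length: float = 0.3,
    step: float = TIME_STEP,
    pad_seconds: float = 1.0,
) -> TFR:
    """Low-band power via a sliding 300 ms Hanning-tapered Fourier transform."""
    freqs = LOW_FREQS if freqs is None else np.asarray(freqs, float)
    n_win = int(round(window_length * epochs.sfreq))
    taper = windows.hann(n_win, sym=False)[None, :]
    out = _sliding_power(epochs, freqs, times, window_length, taper, step, pad_seconds)
    out.estimator["method"] = "hanning"
    out.estimator["smoothing_hz"] = 1.0 / window_length
    return out


def tfr_multitaper(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
    window_length: float = 0.2,
    smoothing: float = 15.0,
    step: float = TIME_STEP,
    pad_seconds: float = 1.0,
) -> TFR:
    """High-band power via sliding-window multitaper (Slepian) estimation.

    ``smoothing`` is the half-bandwidth W in Hz; with window length T the
    taper count is K = 2*T*W - 1 (5 for the default 200 ms, +/-15 Hz).
    """
    freqs = HIGH_FREQS if freqs is None else np.asarray(freqs, float)
    n_tapers = int(round(2.0 * window_length * smoothing - 1.0))
    if n_tapers < 1:
        raise ValueError(
            f"smoothing {smoothing} Hz incompatible with a {window_length} s window "
            "(fewer than one taper)"
        )
    n_win = int(round(window_length * epochs.sfreq))
    nw = window_length * smoothing
    tapers = windows.dpss(n_win, nw, Kmax=n_tapers)
    out = _sliding_power(epochs, freqs, times, window_length, tapers, step, pad_seconds)
    out.estimator["method"] = "multitaper"
    out.estimator["smoothing_hz"] = smoothing
    return out


def average_by_condition(tfr: TFR, cells: Sequence[ConditionCell]) -> TFR:
    """Average per-trial power over trials within each condition cell."""
    if tfr.conditions is None:
        raise ValueError("TFR carries no per-trial condition labels")
    out = np.empty((len(cells),) + tfr.power.shape[1:], tfr.power.dtype)
    for i, cell in enumerate(cells):
        idx = [k for k, c in enumerate(tfr.conditions) if c == cell]
        if not idx:
            raise ValueError(f"no trials in cell {cell.label}")
        out[i] = tfr.power[idx].mean(axis=0)
    return tfr.copy(power=out, conditions=None, cells=list(cells))


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline window (s) in the lock-specific time frame."""

    window: tuple[float, float]

    CUE_DEFAULT = (-0.650, -0.150)
    STIMULUS_DEFAULT = (-2.950, -2.450)

    @classmethod
    def default_for(cls, lock: str) -> "BaselineSpec":
        if lock == "cue":
            return cls(cls.CUE_DEFAULT)
        if lock == "stimulus":
            return cls(cls.STIMULUS_DEFAULT)
        raise ValueError(f"no default baseline for lock mode {lock!r}")


def zbaseline(tfr: TFR, spec: BaselineSpec) -> TFR:
    """Z-score power against the baseline window, per channel and frequency.

    Expects trial-averaged power (one subject).  One mean and one
    standard deviation are estimated per channel-frequency combination,
    pooling the baseline time points of *all* condition cells (or
    trials), and every sample is standardized by them.  Pooling matters:
    cells with fewer trials have noisier trial-averaged baselines, and a
    per-cell sigma would shrink exactly those cells' z values, biasing
    any contrast whose codes correlate with the cell trial counts.
    """
    if tfr.baseline_state == "z":
        raise ValueError("TFR already z-normalized")
    t0, t1 = spec.window
    sel = (tfr.times >= t0 - 1e-9) & (tfr.times <= t1 + 1e-9)
    if sel.sum() < 2:
        raise ValueError(
            f"baseline window [{t0}, {t1}] s covers {int(sel.sum())} spectral "
            "estimates; need at least 2"
        )
    base = tfr.power[..., sel]
    mu = base.mean(axis=(0, -1))[None, ..., None]
    sd = base.std(axis=(0, -1), ddof=0)
    degenerate = np.nonzero(np.isclose(sd, 0.0))
    if degenerate[0].size:
        c, f = degenerate[0][0], degenerate[1][0]
        raise ValueError(
            f"zero baseline standard deviation (channel {tfr.ch_names[c]}, "
            f"{tfr.freqs[f]:g} Hz)"
        )
    z = (tfr.power - mu) / sd[None, ..., None]
    return tfr.copy(power=z.astype(np.float32), baseline_state="z")
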