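"""Synthetic cued-heat EEG and ratings with known ground-truth effects.

Each trial's multichannel signal is 1/f background noise plus a sum of
band-limited oscillatory components.  A component is band-filtered
Gaussian noise (induced, non-phase-locked activity) confined to a time
window by a smooth envelope; its power scales as

    P = P_osc * g_subject * (1 + amplitude * factor_code)

with the trial's predictive-coding factor code (INT, EXP or PE), a
log-normal per-subject gain g and a smooth Gaussian spatial gain map
over the 2-D electrode positions.  The default effect set mirrors the
structure the analysis is meant to recover: theta and gamma power
increasing with stimulus intensity, alpha-to-beta power decreasing with
intensity, alpha-to-beta power increasing with cued expectation
(cue-locked) and gamma power decreasing with the absolute prediction
error (stimulus-locked).

Ratings follow a latent-variable ordinal model: u = b_INT*INT +
b_EXP*EXP + b_PE*PE + subject intercept + Gaussian noise, cut at three
thresholds into the 1-4 aversiveness scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from . import montage
from .design import (
    Trial,
    build_contingency_table,
    factor_codes,
    generate_trials,
    heat_valid_trials,
    trial_cell,
)
from .preprocess import DEFAULT_EPOCH_WINDOW, EpochSet, ramp_shift

__all__ = [
    "BandEffect",
    "RatingModel",
    "SyntheticConfig",
    "default_band_effects",
    "simulate_subject_eeg",
    "simulate_ratings",
    "simulate_study",
]


@dataclass(frozen=True)
class BandEffect:
    """One condition-dependent band-limited oscillatory component."""

    band: tuple[float, float]  # Hz
    window: tuple[float, float]  # s, in the frame given by `lock`
    lock: str  # "cue" or "stimulus"
    factor: str  # "INT", "EXP" or "PE"
    amplitude: float  # fractional power change per unit factor code
    center: tuple[float, float] | None = None  # 2-D topography peak; None = flat
    spread: float = 0.5  # Gaussian topography sigma, head-radius units
    osc_scale: float = 0.8  # oscillation amplitude (baseline, factor code 0)


def default_band_effects() -> list[BandEffect]:
    """The study's ground-truth effect structure.

    Windows are relative to the cue onset or to the stimulus plateau;
    topography centres approximate the midline/centroparietal/occipital
    foci of the corresponding observed effects.
    """
    return [
        BandEffect(band=(2, 7), window=(0.15, 1.05), lock="stimulus",
                   factor="INT", amplitude=0.4, center=(0.0, 0.0)),
        BandEffect(band=(8, 30), window=(0.25, 1.6), lock="stimulus",
                   factor="INT", amplitude=-0.3, center=(0.25, -0.35)),
        BandEffect(band=(46, 100), window=(0.55, 1.6), lock="stimulus",
                   factor="INT", amplitude=0.3, center=(0.2, -0.2)),
        BandEffect(band=(8, 20), window=(0.1, 2.0), lock="cue",
                   factor="EXP", amplitude=0.4, center=(-0.1, -0.55)),
        BandEffect(band=(51, 100), window=(0.05, 1.6), lock="stimulus",
                   factor="PE", amplitude=-0.3, center=(0.0, -0.8)),
    ]


@dataclass(frozen=True)
class RatingModel:
    """Latent ordinal model of the 1-4 aversiveness ratings."""

    beta_int: float = 1.6
    beta_exp: float = 0.3
    beta_pe: float = 0.12
    sigma: float = 0.6  # trial-level latent noise SD
    subject_sigma: float = 0.3  # SD of per-subject intercepts
    thresholds: tuple[float, float, float] = (-0.9, 0.0, 0.9)

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("rating thresholds must be strictly increasing")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level configuration of the synthetic data generator."""

    n_subjects: int = 29
    sfreq: float = 500.0
    channels: tuple[str, ...] | None = None  # None -> the 60-channel layout
    epoch_window: tuple[float, float] = DEFAULT_EPOCH_WINDOW  # trigger-locked, s
    cue_onset_range: tuple[float, float] = (-1.9, -1.5)  # s before trigger
    band_effects: tuple[BandEffect, ...] = field(
        default_factory=lambda: tuple(default_band_effects())
    )
    noise_exponent: float = 1.0  # 1/f^e power slope of the background
    noise_scale: float = 1.0  # background SD (uV)
    subject_sigma: float = 0.2  # log-SD of per-subject oscillation power gain
    ratings: RatingModel = field(default_factory=RatingModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for eff in self.band_effects:
            if not 0.5 <= eff.band[0] < eff.band[1] <= 100.0:
                raise ValueError(f"band {eff.band} outside [1, 100] Hz")
            if eff.lock not in ("cue", "stimulus"):
                raise ValueError(f"unknown effect lock {eff.lock!r}")
            if eff.factor not in ("INT", "EXP", "PE"):
                raise ValueError(f"unknown effect factor {eff.factor!r}")
            worst = _min_power_factor(eff.factor, eff.amplitude)
            if worst <= 0:
                raise ValueError(
                    f"amplitude {eff.amplitude} makes power non-positive "
                    f"(1 + a*code = {worst:.3f}) for factor {eff.factor}"
                )
        if self.band_effects and max(e.band[1] for e in self.band_effects) > self.sfreq / 2:
            raise ValueError("effect band exceeds the Nyquist frequency")

    def replace(self, **changes) -> "SyntheticConfig":
        return replace(self, **changes)

    def channel_list(self) -> list[str]:
        return list(self.channels) if self.channels is not None else montage.default_channels()


def _min_power_factor(factor: str, amplitude: float) -> float:
    codes = {"INT": (-1, 0, 1), "EXP": (-1, 0, 1), "PE": (0, 1, 2)}[factor]
    return min(1.0 + amplitude * c for c in codes)


def default_design(seed: int = 0) -> list[Trial]:
    """The full 4-block session under the 70/60 contingency table."""
    return generate_trials(build_contingency_table(), seed=seed)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sfreq: float, exponent: float, scale: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit-SD scaled by ``scale``."""
    freqs = rfftfreq(n_samples, 1.0 / sfreq)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape + (n_samples,))
    spec = rfft(white, axis=-1) * gain
    x = irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * x / sd


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sfreq: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise (hard spectral mask)."""
    freqs = rfftfreq(n_samples, 1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    white = rng.standard_normal(shape + (n_samples,))
    spec = rfft(white, axis=-1) * mask
    x = irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _envelope(times: np.ndarray, window: tuple[float, float], ramp: float = 0.05) -> np.ndarray:
    """Smooth 0/1 gate over ``window`` with raised-cosine edges."""
    t0, t1 = window
    env = np.zeros_like(times)
    core = (times >= t0 + ramp) & (times <= t1 - ramp)
    env[core] = 1.0
    rise = (times >= t0) & (times < t0 + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - t0) / ramp))
    fall = (times > t1 - ramp) & (times <= t1)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - times[fall]) / ramp))
    return env


def _topography(channels: list[str], center: tuple[float, float] | None, spread: float) -> np.ndarray:
    if center is None:
        return np.ones(len(channels))
    pos = montage.channel_positions(channels)
    xy = np.array([pos[ch] for ch in channels])
    d2 = ((xy - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * spread**2))


def simulate_subject_eeg(
    design: list[Trial], config: SyntheticConfig, subject: int
) -> EpochSet:
    """Simulate one subject's trigger-locked epochs for the heat-valid trials.

    Only trials with a heat cue and a heat stimulus enter (the EEG
    analysis is restricted to the validly cued heat modality).
    Deterministic given ``(config.seed, subject)``.
    """
    trials = heat_valid_trials(design)
    if not trials:
        raise ValueError("design contains no validly cued heat trials")
    channels = config.channel_list()
    sfreq = config.sfreq
    t0, t1 = config.epoch_window
    n_s = int(round((t1 - t0) * sfreq)) + 1
    times = t0 + np.arange(n_s) / sfreq
    n_tr, n_ch = len(trials), len(channels)

    rng = np.random.default_rng([config.seed, 1013, subject])
    cells = [trial_cell(t) for t in trials]
    cue_onset = rng.uniform(*sorted(config.cue_onset_range), size=n_tr)
    shifts = np.array([ramp_shift(c.stimulus_level) for c in cells])

    data = _pink_noise(rng, (n_tr, n_ch), n_s, sfreq, config.noise_exponent,
                       config.noise_scale)

    for eff in config.band_effects:
        g_subj = float(np.exp(config.subject_sigma * rng.standard_normal()))
        topo = _topography(channels, eff.center, eff.spread)
        codes = np.array([factor_codes(c)[eff.factor] for c in cells])
        gain_tr = eff.osc_scale * np.sqrt(g_subj * (1.0 + eff.amplitude * codes))
        offset = cue_onset if eff.lock == "cue" else shifts
        osc = _band_noise(rng, (n_tr, n_ch), n_s, sfreq, eff.band)
        for i in range(n_tr):
            env = _envelope(times, (eff.window[0] + offset[i], eff.window[1] + offset[i]))
            osc[i] *= env * gain_tr[i]
        data += osc * topo[None, :, None]

    return EpochSet(
        data=data.astype(np.float32),
        times=times,
        sfreq=sfreq,
        ch_names=channels,
        conditions=cells,
        lock="trigger",
        reference="common_average",
        cue_onset=cue_onset,
    )


def simulate_ratings(design: list[Trial], config: SyntheticConfig) -> pd.DataFrame:
    """Trial-level ordinal aversiveness ratings for the heat-valid trials.

    Returns a long-form table with columns subject, block, trial,
    cue_level, stimulus_level and rating (1-4).  Deterministic given
    ``config.seed``.
    """
    trials = heat_valid_trials(design)
    model = config.ratings
    rng = np.random.default_rng([config.seed, 2027])
    codes = np.array(
        [
            [factor_codes(trial_cell(t))[f] for f in ("INT", "EXP", "PE")]
            for t in trials
        ]
    )
    betas = np.array([model.beta_int, model.beta_exp, model.beta_pe])
    rows = []
    for subj in range(config.n_subjects):
        intercept = model.subject_sigma * rng.standard_normal()
        latent = codes @ betas + intercept + model.sigma * rng.standard_normal(len(trials))
        rating = 1 + np.searchsorted(np.asarray(model.thresholds), latent)
        for t, r in zip(trials, rating):
            cell = trial_cell(t)
            rows.append(
                {
                    "subject": subj,
                    "block": t.block,
                    "trial": t.trial,
                    "cue_level": cell.cue_level,
                    "stimulus_level": cell.stimulus_level,
                    "rating": int(r),
                }
            )
    return pd.DataFrame(rows)


def simulate_study(
    config: SyntheticConfig, design: list[Trial] | None = None
) -> tuple[list[Trial], list[EpochSet], pd.DataFrame]:
    """Full synthetic study: design, per-subject epochs, ratings."""
    if design is None:
        design = default_design(seed=config.seed)
    epochs = [simulate_subject_eeg(design, config, s) for s in range(config.n_subjects)]
    ratings = simulate_ratings(design, config)
    return design, epochs, ratings
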