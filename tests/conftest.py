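"""Shared fixtures: reduced-scale study configurations.

The scaled conditions keep the full pipeline (design -> simulation ->
preprocessing -> TFR -> contrast -> cluster permutation) but shrink the
montage, sampling rate, grids and trial counts so statistical
simulations complete quickly.
"""

from __future__ import annotations

import numpy as np
import pytest

from cuedpain.design import build_contingency_table, generate_trials
from cuedpain.pipeline import AnalysisConfig, FactorSpec
from cuedpain.simulate import SyntheticConfig

#: connected centro-parieto-occipital subsets of the montage template
CHANNELS_10 = ("C1", "Cz", "C2", "CP1", "CPz", "CP2", "P1", "Pz", "P2", "POz")
CHANNELS_13 = CHANNELS_10 + ("O1", "Oz", "O2")


def small_design(seed: int, n_blocks: int = 1, trials_per_block: int = 72):
    """A short session under the default 70/60 contingency table."""
    return generate_trials(
        build_contingency_table(), n_blocks=n_blocks,
        trials_per_block=trials_per_block, n_catch=0, seed=seed,
    )


def null_synth(seed: int, n_subjects: int = 8) -> SyntheticConfig:
    """Background noise only (all effect amplitudes zero), cue-locked scale."""
    return SyntheticConfig(
        n_subjects=n_subjects, sfreq=250.0, channels=CHANNELS_10,
        epoch_window=(-2.0, 0.15), cue_onset_range=(-1.1, -0.9),
        band_effects=(), seed=seed,
    )


def null_analysis(seed: int, n_perm: int = 200) -> AnalysisConfig:
    """One cue-locked low-band test on a reduced grid."""
    return AnalysisConfig(
        factors=(FactorSpec("EXP", "cue", (0.0, 0.8)),),
        bands=("low",),
        low_freqs=tuple(np.arange(4.0, 25.0, 2.0)),
        n_perm=n_perm, seed=seed,
        baseline_cue=(-0.65, -0.15),
    )


def recovery_synth(seed: int, n_subjects: int = 12) -> SyntheticConfig:
    """Default injected effects at a reduced spatial/temporal scale."""
    return SyntheticConfig(
        n_subjects=n_subjects, sfreq=250.0, channels=CHANNELS_13,
        epoch_window=(-2.9, 1.8), cue_onset_range=(-1.4, -1.0), seed=seed,
    )


def recovery_analysis(seed: int, n_perm: int = 500) -> AnalysisConfig:
    """EXP cue-locked low band and PE stimulus-locked high band."""
    return AnalysisConfig(
        factors=(
            FactorSpec("EXP", "cue", (0.0, 1.6)),
            FactorSpec("PE", "stimulus", (0.0, 1.2)),
        ),
        bands=("low", "high"),
        low_freqs=tuple(np.arange(4.0, 29.0, 2.0)),
        high_freqs=tuple(np.arange(40.0, 101.0, 4.0)),
        n_perm=n_perm, seed=seed,
        baseline_cue=(-0.65, -0.15),
        baseline_stimulus=(-2.6, -2.1),
    )


@pytest.fixture(scope="session")
def default_table():
    return build_contingency_table()


@pytest.fixture(scope="session")
def session_design(default_table):
    return generate_trials(default_table, seed=1)
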