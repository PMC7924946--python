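"""Cue-stimulus contingency design and predictive-coding factor codings.

The experiment crosses a probabilistic visual cue (modality x intensity)
with a heat or picture stimulus.  Cues are equally frequent (six cues,
1/6 of trials each); the cued modality is correct with probability
``p_modality_valid`` (0.70 by default) and the cued intensity level with
probability ``p_intensity_valid`` (0.60 by default).  Heat intensities
are coded ordinally, s in {-1, 0, +1} for 42/46/48 degC, and cue levels
c likewise.  From (s, c) the predictive-coding factors are derived:

==============  =====================================
INT             stimulus intensity, s
EXP             cued (expected) intensity, c
PE              absolute prediction error, ``|s - c|``
signedPE        signed prediction error, ``s - c``
onesidedPE      ``max(s - c, 0)``
==============  =====================================

Over the nine equally weighted heat cells the centred INT, EXP and PE
codes are mutually orthogonal; signedPE is not orthogonal to EXP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "MODALITIES",
    "TEMPERATURES",
    "FACTORS",
    "ConditionCell",
    "FactorCoding",
    "ContingencyTable",
    "Trial",
    "heat_cells",
    "factor_codes",
    "factor_values",
    "build_contingency_table",
    "generate_trials",
    "trials_to_frame",
    "frame_to_trials",
    "factor_table",
]

LEVELS: tuple[int, ...] = (-1, 0, 1)
MODALITIES: tuple[str, str] = ("heat", "picture")
#: target thermode temperature (degC) per ordinal stimulus level
TEMPERATURES: dict[int, float] = {-1: 42.0, 0: 46.0, 1: 48.0}
FACTORS: tuple[str, ...] = ("INT", "EXP", "PE", "signedPE", "onesidedPE")


@dataclass(frozen=True)
class ConditionCell:
    """One cue x stimulus condition cell."""

    stimulus_level: int
    cue_level: int
    modality_stimulus: str = "heat"
    modality_cue: str = "heat"

    def __post_init__(self) -> None:
        if self.stimulus_level not in LEVELS or self.cue_level not in LEVELS:
            raise ValueError(
                f"levels must be in {LEVELS}, got "
                f"(s={self.stimulus_level}, c={self.cue_level})"
            )
        if self.modality_stimulus not in MODALITIES or self.modality_cue not in MODALITIES:
            raise ValueError(f"modalities must be in {MODALITIES}")

    @property
    def label(self) -> str:
        return f"c{self.cue_level:+d}_s{self.stimulus_level:+d}"


@dataclass(frozen=True)
class FactorCoding:
    """All five factor codes of a condition cell."""

    INT: float
    EXP: float
    PE: float
    signedPE: float
    onesidedPE: float

    def __getitem__(self, factor: str) -> float:
        if factor not in FACTORS:
            raise KeyError(factor)
        return getattr(self, factor)


def heat_cells(model: str = "full") -> list[ConditionCell]:
    """The validly-cued-modality heat cells, ordered by (cue, stimulus) level.

    ``model="full"`` gives all 9 cells; ``"reduced"`` drops the lowest
    (42 degC, s = -1) stimulus level, leaving 6 cells with their original
    codes.
    """
    if model not in ("full", "reduced"):
        raise ValueError(f"model must be 'full' or 'reduced', got {model!r}")
    stim_levels = LEVELS if model == "full" else (0, 1)
    return [
        ConditionCell(stimulus_level=s, cue_level=c)
        for c in LEVELS
        for s in stim_levels
    ]


def factor_codes(cell: ConditionCell, model: str = "full") -> FactorCoding:
    """Predictive-coding factor codes of one cell.

    In the reduced (pain-only) model the low stimulus level is excluded,
    not recoded: codes are computed from the original s, c values.
    """
    if model not in ("full", "reduced"):
        raise ValueError(f"model must be 'full' or 'reduced', got {model!r}")
    if model == "reduced" and cell.stimulus_level == -1:
        raise ValueError("reduced model excludes the lowest stimulus level (42 degC)")
    s, c = float(cell.stimulus_level), float(cell.cue_level)
    signed = s - c
    return FactorCoding(
        INT=s,
        EXP=c,
        PE=abs(signed),
        signedPE=signed,
        onesidedPE=max(signed, 0.0),
    )


def factor_values(cells: Sequence[ConditionCell], factor: str, model: str = "full") -> np.ndarray:
    """Vector of codes of ``factor`` over ``cells`` (in order)."""
    return np.array([factor_codes(cell, model)[factor] for cell in cells], float)


def factor_table(model: str = "full") -> pd.DataFrame:
    """All factor codes keyed by condition cell, as a DataFrame."""
    cells = heat_cells(model)
    rows = []
    for cell in cells:
        codes = factor_codes(cell, model)
        rows.append(
            {
                "cue_level": cell.cue_level,
                "stimulus_level": cell.stimulus_level,
                **{f: codes[f] for f in FACTORS},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency table
# ---------------------------------------------------------------------------

CueStim = tuple[str, int]

#: row/column order of the 6x6 table: modality-major, level-minor
CUE_ORDER: tuple[CueStim, ...] = tuple((m, l) for m in MODALITIES for l in LEVELS)


@dataclass(frozen=True)
class ContingencyTable:
    """6 cue x 6 stimulus trial-probability table.

    Rows are cues, columns stimuli, both ordered as ``CUE_ORDER``.
    Every row sums to 1/6 (equally frequent cues); the grand total is 1.
    """

    probabilities: np.ndarray
    p_modality_valid: float
    p_intensity_valid: float

    @property
    def frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(CUE_ORDER, names=["modality", "level"])
        return pd.DataFrame(self.probabilities, index=idx, columns=idx)

    def marginal_modality_valid(self) -> float:
        """P(cue modality == stimulus modality), summed over the table."""
        p = 0.0
        for i, (mc, _) in enumerate(CUE_ORDER):
            for j, (ms, _) in enumerate(CUE_ORDER):
                if mc == ms:
                    p += self.probabilities[i, j]
        return p

    def marginal_intensity_valid(self) -> float:
        """P(cue level == stimulus level), summed over the table."""
        p = 0.0
        for i, (_, lc) in enumerate(CUE_ORDER):
            for j, (_, ls) in enumerate(CUE_ORDER):
                if lc == ls:
                    p += self.probabilities[i, j]
        return p


def build_contingency_table(
    p_modality_valid: float = 0.70, p_intensity_valid: float = 0.60
) -> ContingencyTable:
    """Build the cue x stimulus probability table.

    Modality validity and intensity validity are independent; the invalid
    intensity mass is split equally between the two non-cued levels, and
    invalid-modality trials keep the cued intensity distribution in the
    other modality.

    Raises
    ------
    ValueError
        If either probability is outside the open interval (0, 1).
    """
    for name, p in (("p_modality_valid", p_modality_valid), ("p_intensity_valid", p_intensity_valid)):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    probs = np.zeros((6, 6))
    for i, (mc, lc) in enumerate(CUE_ORDER):
        for j, (ms, ls) in enumerate(CUE_ORDER):
            p_mod = p_modality_valid if ms == mc else (1.0 - p_modality_valid)
            p_lvl = p_intensity_valid if ls == lc else (1.0 - p_intensity_valid) / 2.0
            probs[i, j] = (1.0 / 6.0) * p_mod * p_lvl
    return ContingencyTable(probs, p_modality_valid, p_intensity_valid)


# ---------------------------------------------------------------------------
# trial sequence generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    """One trial of the experimental sequence.

    Catch trials carry a cue but no stimulus (``stimulus is None``).
    """

    block: int
    trial: int
    cue: CueStim
    stimulus: CueStim | None
    is_catch: bool = False


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative ``targets`` to integers summing to ``total``."""
    floors = np.floor(targets).astype(int)
    remainders = targets - floors
    k = int(total - floors.sum())
    if k < 0:
        raise ValueError("targets exceed total")
    order = np.argsort(-remainders, kind="stable")
    floors[order[:k]] += 1
    return floors


def _split_into_blocks(counts: np.ndarray, n_blocks: int, per_block: int) -> np.ndarray:
    """Split per-cell session ``counts`` (sum = n_blocks*per_block) into blocks.

    Greedy least-loaded assignment of the remainder units keeps each
    block's total exactly ``per_block``.
    """
    base = counts // n_blocks
    alloc = np.tile(base[:, None], (1, n_blocks))
    load = alloc.sum(axis=0)
    for cell in range(len(counts)):
        for _ in range(int(counts[cell] - base[cell] * n_blocks)):
            b = int(np.argmin(load))
            alloc[cell, b] += 1
            load[b] += 1
    if not np.all(load == per_block):
        raise AssertionError("block balancing failed")
    return alloc


def _shuffle_max_run(
    items: list, key: callable, rng: np.random.Generator, max_run: int, max_tries: int = 200
) -> list:
    """Shuffle ``items`` so no more than ``max_run`` consecutive share ``key``."""

    def longest_run(seq) -> int:
        best = run = 1
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if key(a) == key(b) else 1
            best = max(best, run)
        return best

    items = list(items)
    for _ in range(max_tries):
        rng.shuffle(items)
        if longest_run(items) <= max_run:
            return items
    # fall back: greedy repair by swapping run offenders elsewhere
    for _ in range(10 * len(items)):
        run = 1
        pos = -1
        for i in range(1, len(items)):
            run = run + 1 if key(items[i]) == key(items[i - 1]) else 1
            if run > max_run:
                pos = i
                break
        if pos < 0:
            return items
        j = int(rng.integers(len(items)))
        items[pos], items[j] = items[j], items[pos]
    return items  # pragma: no cover - pathological inputs only


def generate_trials(
    table: ContingencyTable,
    n_blocks: int = 4,
    trials_per_block: int = 126,
    n_catch: int = 4,
    seed: int = 0,
    max_cue_run: int = 3,
) -> list[Trial]:
    """Generate a pseudorandomized trial sequence.

    Cell counts follow largest-remainder rounding of the table
    probabilities times the session trial count, applied within each cue
    row (so every cue occurs equally often), then balanced across blocks.
    Within a block the order is shuffled under the constraint that no
    more than ``max_cue_run`` consecutive trials share a cue; ``n_catch``
    catch trials per block (cue only, no stimulus) are interleaved at
    random positions.  Deterministic given ``seed``.
    """
    if trials_per_block % 6 != 0:
        raise ValueError("trials_per_block must be divisible by 6 (equal cue frequency)")
    rng = np.random.default_rng(seed)
    n_total = n_blocks * trials_per_block
    per_row = n_total // 6

    # session-level per-cell counts, one largest-remainder pass per cue row
    session = np.zeros((6, 6), int)
    for i in range(6):
        row_targets = table.probabilities[i] * n_total
        if abs(row_targets.sum() - per_row) > 1e-9:
            raise ValueError("table rows must sum to 1/6")
        session[i] = _largest_remainder(row_targets, per_row)

    # distribute each row's cells over blocks, keeping per-block rows equal
    block_counts = np.zeros((n_blocks, 6, 6), int)
    for i in range(6):
        block_counts[:, i, :] = _split_into_blocks(
            session[i], n_blocks, trials_per_block // 6
        ).T

    trials: list[Trial] = []
    for b in range(n_blocks):
        block_items: list[tuple[CueStim, CueStim]] = []
        for i, cue in enumerate(CUE_ORDER):
            for j, stim in enumerate(CUE_ORDER):
                block_items.extend([(cue, stim)] * int(block_counts[b, i, j]))
        ordered = _shuffle_max_run(block_items, key=lambda x: x[0], rng=rng, max_run=max_cue_run)
        seq: list[Trial] = [
            Trial(block=b + 1, trial=t + 1, cue=cue, stimulus=stim)
            for t, (cue, stim) in enumerate(ordered)
        ]
        # interleave catch trials (cue only) at random positions
        for _ in range(n_catch):
            pos = int(rng.integers(len(seq) + 1))
            cue = CUE_ORDER[int(rng.integers(6))]
            seq.insert(pos, Trial(block=b + 1, trial=0, cue=cue, stimulus=None, is_catch=True))
        seq = [
            Trial(block=t.block, trial=t_i + 1, cue=t.cue, stimulus=t.stimulus, is_catch=t.is_catch)
            for t_i, t in enumerate(seq)
        ]
        trials.extend(seq)
    return trials


def heat_valid_trials(trials: Iterable[Trial]) -> list[Trial]:
    """Non-catch trials where a heat stimulus was cued as heat."""
    return [
        t
        for t in trials
        if not t.is_catch
        and t.stimulus is not None
        and t.cue[0] == "heat"
        and t.stimulus[0] == "heat"
    ]


def trial_cell(trial: Trial) -> ConditionCell:
    """The condition cell of a non-catch trial."""
    if trial.is_catch or trial.stimulus is None:
        raise ValueError("catch trials have no condition cell")
    return ConditionCell(
        stimulus_level=trial.stimulus[1],
        cue_level=trial.cue[1],
        modality_stimulus=trial.stimulus[0],
        modality_cue=trial.cue[0],
    )


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Trial sequence as a DataFrame (CSV-ready)."""
    rows = []
    for t in trials:
        rows.append(
            {
                "block": t.block,
                "trial": t.trial,
                "cue_modality": t.cue[0],
                "cue_level": t.cue[1],
                "stim_modality": "" if t.stimulus is None else t.stimulus[0],
                "stim_level": "" if t.stimulus is None else t.stimulus[1],
                "is_catch": int(t.is_catch),
            }
        )
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> list[Trial]:
    """Inverse of :func:`trials_to_frame`."""
    out = []
    for _, r in frame.iterrows():
        catch = bool(int(r["is_catch"]))
        stim = None if catch else (str(r["stim_modality"]), int(r["stim_level"]))
        out.append(
            Trial(
                block=int(r["block"]),
                trial=int(r["trial"]),
                cue=(str(r["cue_modality"]), int(r["cue_level"])),
                stimulus=stim,
                is_catch=catch,
            )
        )
    return out
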