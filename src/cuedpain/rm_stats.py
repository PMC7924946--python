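"""Single-df repeated-measures contrasts and the behavioral rating ANOVA.

Every factor of the predictive-coding design (INT, EXP, PE, signedPE,
onesidedPE) enters as a single-degree-of-freedom linear contrast over
the condition cells: the factor codes are centred and scaled to unit
norm, each subject's cell means are projected onto them (per-subject
contrast score d_i), and

    F = n * mean(d)^2 / var(d),        df = (1, n - 1),

which is the square of the paired one-sample t statistic on the d
scores.  Per-subject intercepts cancel in the contrast, so this is the
within-subject ("repeated measures") main-effect test of the factor's
linear trend; all F statistics consequently carry df (1, n-1), e.g.
(1, 28) at the full sample of 29 subjects.  The per-sample slope sign
(sign of mean(d)) records the direction of the effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ConditionCell, FACTORS, factor_values, heat_cells

__all__ = [
    "ConditionAverage",
    "FStatMap",
    "contrast_weights",
    "contrast_scores",
    "contrast_F",
    "behavioral_anova",
    "crit_F",
    "ratings_cell_matrix",
]


@dataclass
class ConditionAverage:
    """Per-subject condition-cell averages of z power.

    ``z`` has shape (subjects, cells, channels, freqs, times); ``cells``
    lists the condition cells in axis order (9 for the full model, 6 for
    the reduced pain model).
    """

    z: np.ndarray
    cells: list[ConditionCell]
    ch_names: list[str]
    freqs: np.ndarray
    times: np.ndarray
    model: str = "full"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        expected = (len(self.cells), len(self.ch_names), len(self.freqs), len(self.times))
        if self.z.ndim != 5 or self.z.shape[1:] != expected:
            raise ValueError(
                f"z must be (subjects, {expected[0]} cells, {expected[1]} channels, "
                f"{expected[2]} freqs, {expected[3]} times); got {self.z.shape}"
            )
        n_cells = {"full": 9, "reduced": 6, "custom": None}.get(self.model, -1)
        if n_cells == -1:
            raise ValueError(f"unknown model {self.model!r}")
        if n_cells is not None and len(self.cells) != n_cells:
            raise ValueError(f"{self.model} model requires {n_cells} cells")

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    def crop(self, window: tuple[float, float] | None = None,
             band: tuple[float, float] | None = None) -> "ConditionAverage":
        tol = 1e-9
        tsel = np.ones(len(self.times), bool)
        if window is not None:
            tsel &= (self.times >= window[0] - tol) & (self.times <= window[1] + tol)
        fsel = np.ones(len(self.freqs), bool)
        if band is not None:
            fsel &= (self.freqs >= band[0] - tol) & (self.freqs <= band[1] + tol)
        return ConditionAverage(
            z=self.z[:, :, :, fsel][:, :, :, :, tsel],
            cells=self.cells,
            ch_names=self.ch_names,
            freqs=self.freqs[fsel],
            times=self.times[tsel],
            model=self.model,
        )


@dataclass
class FStatMap:
    """Per-sample F values and contrast-slope signs for one factor."""

    F: np.ndarray  # channels x freqs x times (or any sample shape)
    slope: np.ndarray  # in {-1, 0, +1}, same shape
    df: tuple[int, int]
    factor: str = ""


def contrast_weights(cells: Sequence[ConditionCell], factor: str, model: str = "full") -> np.ndarray:
    """Centred, unit-norm contrast weights of ``factor`` over ``cells``."""
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; choose from {FACTORS}")
    w = factor_values(cells, factor, "full" if model == "custom" else model)
    w = w - w.mean()
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError(f"factor {factor} is constant over the given cells")
    return w / norm


def contrast_scores(y: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-subject contrast scores d_i = sum_j w_j y_ij.

    ``y`` has subjects on axis 0 and cells on axis 1; trailing axes are
    carried through.
    """
    y = np.asarray(y, float)
    return np.tensordot(weights, np.moveaxis(y, 1, 0), axes=(0, 0))


def _f_from_scores(d: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[axis]
    mean = d.mean(axis=axis)
    var = d.var(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = n * mean**2 / var
    if np.any(var == 0):
        F = np.where(var == 0, np.where(mean == 0, 0.0, np.inf), F)
        if np.any((var == 0) & (mean != 0)):
            warnings.warn("zero contrast-score variance; F reported as +inf",
                          RuntimeWarning)
    return F, np.sign(mean)


def contrast_F(data: ConditionAverage | np.ndarray, factor: str,
               cells: Sequence[ConditionCell] | None = None,
               model: str = "full") -> FStatMap:
    """Repeated-measures single-df F map of a factor's linear contrast.

    ``data`` is a :class:`ConditionAverage` or a plain array with
    (subjects, cells, ...) layout (then ``cells`` must be given).
    """
    if isinstance(data, ConditionAverage):
        y, cells, model = data.z, data.cells, data.model
    else:
        y = np.asarray(data, float)
        if cells is None:
            raise ValueError("cells must be provided with a plain array")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    w = contrast_weights(cells, factor, model)
    d = contrast_scores(y, w)
    # scores are weighted sums of ~unit-weight terms; cancellation residue
    # below machine precision relative to the data scale is exactly zero
    tiny = 1e-12 * max(np.abs(y).max(), 1e-300)
    d[np.abs(d) < tiny] = 0.0
    F, slope = _f_from_scores(d)
    return FStatMap(F=F, slope=slope, df=(1, n - 1), factor=factor)


def crit_F(alpha: float, df1: int, df2: int) -> float:
    """Upper-``alpha`` quantile of the F(df1, df2) distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df1, df2))


def ratings_cell_matrix(ratings: pd.DataFrame, model: str = "full") -> tuple[np.ndarray, list[ConditionCell]]:
    """Subjects x cells matrix of mean ratings from a long-form table.

    The table needs columns ``subject``, ``cue_level``, ``stimulus_level``
    and ``rating``.  Missing subject-cell combinations raise (ratings are
    never imputed).
    """
    cells = heat_cells(model)
    if model == "reduced":
        ratings = ratings[ratings["stimulus_level"] != -1]
    grouped = ratings.groupby(["subject", "cue_level", "stimulus_level"])["rating"].mean()
    subjects = sorted(ratings["subject"].unique())
    mat = np.full((len(subjects), len(cells)), np.nan)
    for i, subj in enumerate(subjects):
        for j, cell in enumerate(cells):
            key = (subj, cell.cue_level, cell.stimulus_level)
            if key not in grouped.index:
                raise ValueError(f"subject {subj} has no trials in cell {cell.label}")
            mat[i, j] = grouped.loc[key]
    return mat, cells


def behavioral_anova(ratings: pd.DataFrame | np.ndarray, model: str = "full",
                     cells: Sequence[ConditionCell] | None = None) -> pd.DataFrame:
    """Repeated-measures ANOVA of mean aversiveness ratings.

    Accepts a long-form trial table (see :func:`ratings_cell_matrix`) or
    a ready subjects x cells matrix with ``cells`` given.  Returns one
    row per factor (INT, EXP, PE) with F, df and the parametric p value
    from F(1, n-1).
    """
    if isinstance(ratings, pd.DataFrame):
        mat, cells = ratings_cell_matrix(ratings, model)
    else:
        mat = np.asarray(ratings, float)
        if cells is None:
            cells = heat_cells(model)
        if mat.shape[1] != len(cells):
            raise ValueError(f"expected {len(cells)} cells, got {mat.shape[1]}")
    if np.isnan(mat).any():
        raise ValueError("missing cells in the rating matrix (no imputation)")
    rows = []
    for factor in ("INT", "EXP", "PE"):
        res = contrast_F(mat, factor, cells=cells, model=model)
        F = float(np.squeeze(res.F))
        p = float(stats.f.sf(F, *res.df))
        rows.append({"factor": factor, "F": F, "df1": res.df[0], "df2": res.df[1],
                     "p": p, "slope": int(np.squeeze(res.slope))})
    return pd.DataFrame(rows)
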