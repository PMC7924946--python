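"""Spatio-spectro-temporal cluster-mass Monte-Carlo permutation testing.

Supra-threshold samples of a channels x frequencies x times F map are
clustered under a combined adjacency rule: neighboring time steps,
neighboring frequency bins (+/- one grid step) and neighboring channels
(a shipped montage template).  A sample additionally needs at least one
channel neighbor that itself exceeds the threshold ("significant
neighbor in electrode space"); on a single-channel montage this spatial
constraint is vacuous and clustering reduces to plain 2-D
time-frequency clustering.  Clusters are split by the sign of the
contrast slope before connectivity, and a cluster's mass is the sum of
its F values.

The Monte-Carlo reference distribution permutes the condition-cell
labels independently within every subject (cells are exchangeable
within subject under the null of no factor effect) and records, per
permutation, the maximum cluster mass over clusters of *both* signs.
Each observed cluster is compared against this single max-statistic
distribution, which controls the family-wise error rate over the whole
tested volume and both effect directions; p values use the add-one
Monte-Carlo estimator (1 + b) / (1 + m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .montage import ChannelNeighborhood
from .rm_stats import ConditionAverage, FStatMap, contrast_F, contrast_weights, crit_F

__all__ = ["ClusterResult", "ClusterTest", "find_clusters", "permutation_test"]


@dataclass
class ClusterResult:
    """One connected supra-threshold cluster."""

    members: np.ndarray  # (n, 3) int array of (channel, freq, time) indices
    sign: int
    mass: float
    p: float | None = None
    ch_names: list[str] = field(default_factory=list)
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None
    peak: dict | None = None  # channel, freq, time, F at the argmax of F

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def channels(self) -> list[str]:
        return sorted({self.ch_names[c] for c in self.members[:, 0]})

    @property
    def freq_range(self) -> tuple[float, float]:
        f = self.freqs[self.members[:, 1]]
        return float(f.min()), float(f.max())

    @property
    def time_range(self) -> tuple[float, float]:
        t = self.times[self.members[:, 2]]
        return float(t.min()), float(t.max())

    def summary(self) -> dict:
        out = {
            "sign": self.sign,
            "mass": round(float(self.mass), 3),
            "p": None if self.p is None else round(float(self.p), 5),
            "n_samples": self.n_members,
            "time_range_s": [round(v, 4) for v in self.time_range],
            "freq_range_hz": list(self.freq_range),
            "n_channels": len(self.channels),
            "channels": self.channels,
        }
        if self.peak is not None:
            out["peak"] = self.peak
        return out


def _neighbor_index_lists(neighbors: ChannelNeighborhood, ch_names: list[str]) -> list[np.ndarray]:
    missing = [ch for ch in ch_names if ch not in neighbors]
    if missing:
        raise KeyError(f"channels missing from the neighborhood template: {missing}")
    return neighbors.index_lists(ch_names)


def find_clusters(
    fmap: FStatMap,
    threshold: float,
    neighbors: ChannelNeighborhood,
    ch_names: list[str],
    freqs: np.ndarray,
    times: np.ndarray,
    min_channel_neighbors: int = 1,
) -> list[ClusterResult]:
    """Partition supra-threshold samples into sign-split connected clusters.

    The electrode-space constraint (``min_channel_neighbors`` supra-
    threshold channel neighbors at the same frequency and time,
    evaluated on the unsigned supra-threshold mask in a single pass) is
    applied before connectivity; it is skipped on a single-channel map.
    Returns clusters without p values, sorted by decreasing mass.
    """
    F, slope = np.asarray(fmap.F), np.asarray(fmap.slope)
    if F.shape != (len(ch_names), len(freqs), len(times)):
        raise ValueError("F map shape inconsistent with channel/freq/time axes")
    if not np.all(np.isfinite(F)):
        raise ValueError("F map contains non-finite values")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    supra = F > threshold
    nb_idx = _neighbor_index_lists(neighbors, ch_names)

    if len(ch_names) > 1 and min_channel_neighbors > 0:
        nb_count = np.zeros_like(F, dtype=int)
        for c, nbs in enumerate(nb_idx):
            if len(nbs):
                nb_count[c] = supra[nbs].sum(axis=0)
        keep = supra & (nb_count >= min_channel_neighbors)
    else:
        keep = supra

    clusters: list[ClusterResult] = []
    for sign in (1, -1):
        mask = keep & (slope == sign)
        clusters.extend(_connected_clusters(F, mask, sign, nb_idx, ch_names, freqs, times))
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def _connected_clusters(F, mask, sign, nb_idx, ch_names, freqs, times) -> list[ClusterResult]:
    n_ch, n_f, n_t = mask.shape
    flat = np.flatnonzero(mask.ravel())
    if flat.size == 0:
        return []
    node_of = -np.ones(mask.size, dtype=np.int64)
    node_of[flat] = np.arange(flat.size)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []

    # time adjacency: (c, f, t) -- (c, f, t+1)
    pair = mask[:, :, :-1] & mask[:, :, 1:]
    if pair.any():
        idx = np.argwhere(pair)
        a = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), mask.shape)
        b = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2] + 1), mask.shape)
        rows.append(node_of[a]); cols.append(node_of[b])
    # frequency adjacency: (c, f, t) -- (c, f+1, t)
    pair = mask[:, :-1, :] & mask[:, 1:, :]
    if pair.any():
        idx = np.argwhere(pair)
        a = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), mask.shape)
        b = np.ravel_multi_index((idx[:, 0], idx[:, 1] + 1, idx[:, 2]), mask.shape)
        rows.append(node_of[a]); cols.append(node_of[b])
    # channel adjacency at the same (f, t)
    for c, nbs in enumerate(nb_idx):
        for c2 in nbs:
            if c2 <= c:
                continue
            pair = mask[c] & mask[c2]
            if pair.any():
                idx = np.argwhere(pair)
                a = np.ravel_multi_index((np.full(len(idx), c), idx[:, 0], idx[:, 1]), mask.shape)
                b = np.ravel_multi_index((np.full(len(idx), c2), idx[:, 0], idx[:, 1]), mask.shape)
                rows.append(node_of[a]); cols.append(node_of[b])

    n = flat.size
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = sparse.coo_matrix((np.ones(len(r), bool), (r, c)), shape=(n, n))
    else:
        graph = sparse.coo_matrix((n, n), dtype=bool)
    _, labels = connected_components(graph, directed=False)

    members_3d = np.array(np.unravel_index(flat, mask.shape)).T  # (n, 3)
    f_vals = F.ravel()[flat]
    out = []
    for lab in np.unique(labels):
        sel = labels == lab
        mem = members_3d[sel]
        fv = f_vals[sel]
        peak_i = int(np.argmax(fv))
        peak = {
            "channel": ch_names[mem[peak_i, 0]],
            "freq_hz": float(freqs[mem[peak_i, 1]]),
            "time_s": float(times[mem[peak_i, 2]]),
            "F": float(fv[peak_i]),
        }
        out.append(
            ClusterResult(
                members=mem, sign=sign, mass=float(fv.sum()),
                ch_names=list(ch_names), freqs=np.asarray(freqs, float),
                times=np.asarray(times, float), peak=peak,
            )
        )
    return out


@dataclass
class ClusterTest:
    """Result of a cluster-mass permutation test."""

    clusters: list[ClusterResult]
    null_max_mass: np.ndarray
    threshold: float
    factor: str
    n_perm: int
    seed: int | None
    df: tuple[int, int]

    def significant(self, alpha: float = 0.05) -> list[ClusterResult]:
        return [c for c in self.clusters if c.p is not None and c.p <= alpha]


def _within_subject_permutations(
    rng: np.random.Generator, n_subjects: int, n_cells: int, n_perm: int
) -> np.ndarray:
    """(n_perm, n_subjects, n_cells) cell-label permutations per subject."""
    perms = np.empty((n_perm, n_subjects, n_cells), dtype=np.int64)
    for p in range(n_perm):
        for s in range(n_subjects):
            perms[p, s] = rng.permutation(n_cells)
    return perms


def _exhaustive_permutations(n_subjects: int, n_cells: int) -> np.ndarray:
    from itertools import permutations, product

    cell_perms = [np.array(p) for p in permutations(range(n_cells))]
    combos = list(product(range(len(cell_perms)), repeat=n_subjects))
    out = np.empty((len(combos), n_subjects, n_cells), dtype=np.int64)
    for i, combo in enumerate(combos):
        for s, k in enumerate(combo):
            out[i, s] = cell_perms[k]
    return out


def permutation_test(
    data: ConditionAverage,
    factor: str,
    neighbors: ChannelNeighborhood,
    n_perm: int = 1000,
    seed: int | None = 0,
    threshold: float | None = None,
    cluster_alpha: float = 0.05,
    window: tuple[float, float] | None = None,
    band: tuple[float, float] | None = None,
    min_channel_neighbors: int = 1,
    batch: int = 64,
) -> ClusterTest:
    """Monte-Carlo cluster-mass test of a factor's within-subject contrast.

    ``threshold`` defaults to the upper-``cluster_alpha`` F(1, n-1)
    quantile (F = 4.196 at alpha 0.05 and 29 subjects).  ``window`` and
    ``band`` crop the tested time and frequency extent first.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    data = data.crop(window=window, band=band)
    n_sub, n_cells = data.z.shape[:2]
    if threshold is None:
        threshold = crit_F(cluster_alpha, 1, n_sub - 1)

    observed = contrast_F(data, factor)
    clusters = find_clusters(
        observed, threshold, neighbors, data.ch_names, data.freqs, data.times,
        min_channel_neighbors=min_channel_neighbors,
    )

    total = math.factorial(n_cells) ** n_sub
    rng = np.random.default_rng(seed)
    if n_perm > total:
        warnings.warn(
            f"n_perm={n_perm} exceeds the {total} distinct within-subject "
            "permutations; enumerating exhaustively", RuntimeWarning,
        )
        perms = _exhaustive_permutations(n_sub, n_cells)
    else:
        perms = _within_subject_permutations(rng, n_sub, n_cells, n_perm)
    m = len(perms)

    w = contrast_weights(data.cells, factor, data.model)
    y = data.z.reshape(n_sub, n_cells, -1).astype(np.float64)
    sample_shape = data.z.shape[2:]

    null_max = np.empty(m)
    for a in range(0, m, batch):
        b = min(a + batch, m)
        W = w[perms[a:b]]  # (batch, subj, cells)
        d = np.einsum("psc,scm->psm", W, y)
        mean = d.mean(axis=1)
        var = d.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            Fp = n_sub * mean**2 / var
        Fp = np.nan_to_num(Fp, nan=0.0, posinf=0.0)
        slope_p = np.sign(mean)
        for i in range(b - a):
            cl = find_clusters(
                FStatMap(F=Fp[i].reshape(sample_shape), slope=slope_p[i].reshape(sample_shape),
                         df=(1, n_sub - 1), factor=factor),
                threshold, neighbors, data.ch_names, data.freqs, data.times,
                min_channel_neighbors=min_channel_neighbors,
            )
            null_max[a + i] = max((abs(c.mass) for c in cl), default=0.0)

    for c in clusters:
        c.p = float((1 + np.sum(null_max >= abs(c.mass))) / (1 + m))
    return ClusterTest(
        clusters=clusters, null_max_mass=null_max, threshold=float(threshold),
        factor=factor, n_perm=m, seed=seed, df=(1, n_sub - 1),
    )
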