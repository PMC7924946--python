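"""EEG montage: 60-channel extended 10-20 layout, 2-D positions, adjacency.

The shipped template (``data/neighbors_1020_61.json``) holds the 60 scalp
electrodes of a 64-channel active-electrode cap (EOG/EMG electrodes and
the Iz ground excluded) plus the recording reference FCz, each with a 2-D
position (azimuthal projection of the standard 10-20 sphere, unit head
radius) and a symmetric neighbor list from a Delaunay triangulation of
those positions (long edges pruned).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelNeighborhood",
    "default_neighborhood",
    "default_channels",
    "channel_positions",
    "build_delaunay_neighbors",
]

_TEMPLATE = "neighbors_1020_61.json"

#: the 60 recorded scalp channels (FCz was the reference, Iz the ground)
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


class ChannelNeighborhood:
    """Symmetric channel adjacency (no self-neighbors)."""

    def __init__(self, neighbors: dict[str, set[str]]):
        self.neighbors = {ch: set(nb) for ch, nb in neighbors.items()}
        self._validate()

    def _validate(self) -> None:
        for ch, nbs in self.neighbors.items():
            if ch in nbs:
                raise ValueError(f"self-neighbor at {ch}")
            for nb in nbs:
                if nb not in self.neighbors or ch not in self.neighbors[nb]:
                    raise ValueError(f"asymmetric adjacency: {ch} -> {nb}")

    @property
    def channels(self) -> list[str]:
        return list(self.neighbors)

    def __contains__(self, ch: str) -> bool:
        return ch in self.neighbors

    def __getitem__(self, ch: str) -> set[str]:
        return self.neighbors[ch]

    def subset(self, channels: list[str]) -> "ChannelNeighborhood":
        """Adjacency restricted to ``channels`` (edges within the subset)."""
        missing = [ch for ch in channels if ch not in self.neighbors]
        if missing:
            raise KeyError(f"channels not in template: {missing}")
        keep = set(channels)
        return ChannelNeighborhood(
            {ch: self.neighbors[ch] & keep for ch in channels}
        )

    def index_lists(self, channels: list[str]) -> list[np.ndarray]:
        """Per-channel arrays of neighbor indices within ``channels``."""
        pos = {ch: i for i, ch in enumerate(channels)}
        return [
            np.array(sorted(pos[nb] for nb in self.neighbors[ch] if nb in pos), int)
            for ch in channels
        ]

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelNeighborhood":
        with open(path) as fh:
            doc = json.load(fh)
        return cls({ch: set(nb) for ch, nb in doc["neighbors"].items()})

    def to_json(self, path: str | Path, positions: dict[str, tuple[float, float]] | None = None) -> None:
        doc: dict = {"neighbors": {ch: sorted(nb) for ch, nb in sorted(self.neighbors.items())}}
        if positions is not None:
            doc["positions"] = {ch: list(map(float, xy)) for ch, xy in sorted(positions.items())}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def _template_doc() -> dict:
    with resources.files("cuedpain.data").joinpath(_TEMPLATE).open() as fh:
        return json.load(fh)


def default_neighborhood() -> ChannelNeighborhood:
    """The shipped 61-channel adjacency template."""
    return ChannelNeighborhood({ch: set(nb) for ch, nb in _template_doc()["neighbors"].items()})


def default_channels() -> list[str]:
    """The 60 recorded scalp channels, in template order."""
    return list(DEFAULT_CHANNELS)


def channel_positions(channels: list[str] | None = None) -> dict[str, np.ndarray]:
    """2-D positions (unit head radius) for ``channels`` (default: all)."""
    pos = {ch: np.asarray(xy, float) for ch, xy in _template_doc()["positions"].items()}
    if channels is None:
        return pos
    missing = [ch for ch in channels if ch not in pos]
    if missing:
        raise KeyError(f"channels without template positions: {missing}")
    return {ch: pos[ch] for ch in channels}


def build_delaunay_neighbors(
    positions: dict[str, tuple[float, float]], max_edge: float = 0.62
) -> ChannelNeighborhood:
    """Adjacency from a Delaunay triangulation of 2-D positions.

    Edges longer than ``max_edge`` (in the same units as the positions)
    are pruned; these arise along the head rim where the triangulation
    connects distant temporal/frontal sites.
    """
    from scipy.spatial import Delaunay

    labels = list(positions)
    pts = np.array([positions[ch] for ch in labels], float)
    if len(labels) < 3:
        pairs = {(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))}
    else:
        tri = Delaunay(pts)
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((simplex[a], simplex[b]))
                    pairs.add((i, j))
    neighbors: dict[str, set[str]] = {ch: set() for ch in labels}
    for i, j in pairs:
        if np.linalg.norm(pts[i] - pts[j]) <= max_edge:
            neighbors[labels[i]].add(labels[j])
            neighbors[labels[j]].add(labels[i])
    return ChannelNeighborhood(neighbors)
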