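"""Regenerate the shipped electrode neighborhood template.

Positions come from mne's bundled standard 10-20 montage (azimuthal
projection to 2-D, scaled to unit head radius); adjacency is a Delaunay
triangulation with long rim edges pruned.  Run from the repo root:

    python scripts/build_neighbor_template.py
"""

from pathlib import Path

import numpy as np

import mne

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from cuedpain.montage import DEFAULT_CHANNELS, build_delaunay_neighbors  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src" / "cuedpain" / "data" / "neighbors_1020_61.json"


def azimuthal_2d(pos3d: np.ndarray) -> np.ndarray:
    """Project a 3-D head-sphere position to the 2-D plane (polar azimuthal)."""
    x, y, z = pos3d / np.linalg.norm(pos3d)
    theta = np.arccos(np.clip(z, -1, 1))  # inclination from vertex
    phi = np.arctan2(y, x)
    # scale: Cz (theta=0) at origin, the theta=pi/2 ring at radius 1
    r = theta / (np.pi / 2)
    return np.array([r * np.cos(phi), r * np.sin(phi)])


def main() -> None:
    labels = list(DEFAULT_CHANNELS) + ["FCz"]
    montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    missing = [ch for ch in labels if ch not in pos3d]
    if missing:
        raise SystemExit(f"labels missing from montage: {missing}")
    positions = {ch: azimuthal_2d(np.asarray(pos3d[ch])) for ch in labels}
    nb = build_delaunay_neighbors({ch: tuple(xy) for ch, xy in positions.items()})
    counts = {ch: len(nb[ch]) for ch in labels}
    print("neighbor count: min", min(counts.values()), "max", max(counts.values()))
    isolated = [ch for ch, n in counts.items() if n == 0]
    if isolated:
        raise SystemExit(f"isolated channels: {isolated}")
    nb.to_json(OUT, positions={ch: tuple(xy) for ch, xy in positions.items()})
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
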