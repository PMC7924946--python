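"""HDF5 array-container and CSV/JSON input-output.

Layout of the HDF5 container for an epoch set:
``/data`` (trials x channels x samples), ``/time``, ``/labels``
(channel names), ``/conditions`` (trials x 2 of cue/stimulus level,
-9 where absent) plus scalar attributes.  TFRs store ``/power``,
``/freqs``, ``/times``, ``/channels`` and estimator/baseline
attributes; condition averages store ``/z`` with the cell table.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .design import ConditionCell
from .preprocess import EpochSet
from .rm_stats import ConditionAverage
from .tfr import TFR

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_tfr",
    "load_tfr",
    "save_condition_average",
    "load_condition_average",
    "read_brainvision",
]

_NONE = -9


def _cells_to_array(cells) -> np.ndarray:
    out = np.full((len(cells), 2), _NONE, np.int8)
    for i, c in enumerate(cells):
        if c is not None:
            out[i] = (c.cue_level, c.stimulus_level)
    return out


def _cells_from_array(arr) -> list[ConditionCell | None]:
    return [
        None if row[0] == _NONE else ConditionCell(stimulus_level=int(row[1]), cue_level=int(row[0]))
        for row in arr
    ]


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time", data=epochs.times)
        f.create_dataset("labels", data=np.array(epochs.ch_names, dtype="S16"))
        f.create_dataset("conditions", data=_cells_to_array(epochs.conditions))
        f.create_dataset("lock_shift", data=epochs.lock_shift)
        if epochs.cue_onset is not None:
            f.create_dataset("cue_onset", data=epochs.cue_onset)
        f.attrs.update(sfreq=epochs.sfreq, lock=epochs.lock, reference=epochs.reference)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["time"][()],
            sfreq=float(f.attrs["sfreq"]),
            ch_names=[s.decode() for s in f["labels"][()]],
            conditions=_cells_from_array(f["conditions"][()]),
            lock=str(f.attrs["lock"]),
            reference=str(f.attrs["reference"]),
            cue_onset=f["cue_onset"][()] if "cue_onset" in f else None,
            lock_shift=f["lock_shift"][()],
        )


def save_tfr(path: str | Path, tfr: TFR) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power, compression="gzip", compression_opts=1)
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("times", data=tfr.times)
        f.create_dataset("channels", data=np.array(tfr.ch_names, dtype="S16"))
        if tfr.conditions is not None:
            f.create_dataset("conditions", data=_cells_to_array(tfr.conditions))
        if tfr.cells is not None:
            f.create_dataset("cells", data=_cells_to_array(tfr.cells))
        f.attrs["estimator"] = json.dumps(tfr.estimator)
        f.attrs["baseline_state"] = tfr.baseline_state


def load_tfr(path: str | Path) -> TFR:
    with h5py.File(path, "r") as f:
        cells = _cells_from_array(f["cells"][()]) if "cells" in f else None
        conds = _cells_from_array(f["conditions"][()]) if "conditions" in f else None
        return TFR(
            power=f["power"][()],
            freqs=f["freqs"][()],
            times=f["times"][()],
            ch_names=[s.decode() for s in f["channels"][()]],
            estimator=json.loads(f.attrs["estimator"]),
            baseline_state=str(f.attrs["baseline_state"]),
            conditions=conds,
            cells=cells,
        )


def save_condition_average(path: str | Path, avg: ConditionAverage) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=avg.z, compression="gzip", compression_opts=1)
        f.create_dataset("freqs", data=avg.freqs)
        f.create_dataset("times", data=avg.times)
        f.create_dataset("channels", data=np.array(avg.ch_names, dtype="S16"))
        f.create_dataset("cells", data=_cells_to_array(avg.cells))
        f.attrs["model"] = avg.model


def load_condition_average(path: str | Path) -> ConditionAverage:
    with h5py.File(path, "r") as f:
        return ConditionAverage(
            z=f["z"][()],
            cells=[c for c in _cells_from_array(f["cells"][()]) if c is not None],
            ch_names=[s.decode() for s in f["channels"][()]],
            freqs=f["freqs"][()],
            times=f["times"][()],
            model=str(f.attrs["model"]),
        )


def read_brainvision(vhdr_path: str | Path) -> tuple[np.ndarray, float, list[str], np.ndarray]:
    """Continuous data, sfreq, channel names and event times from a
    BrainVision (.vhdr/.eeg/.vmrk) recording.  Requires mne."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    events, _ = mne.events_from_annotations(raw, verbose="error")
    trigger_times = events[:, 0] / raw.info["sfreq"]
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names), trigger_times
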