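"""HDF5 containers for recordings and epoch sets, with sidecar events TSV."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .oddball import read_events_tsv, write_events_tsv
from .preprocess import EpochSet
from .simulate import Recording


def save_recording(recording: Recording, path, events_path=None) -> None:
    """Write a recording to HDF5 plus a sidecar events TSV.

    ``events_path`` defaults to the HDF5 path with an ``_events.tsv``
    suffix.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip",
                         compression_opts=1)
        f.attrs["rate_hz"] = recording.rate_hz
        f.create_dataset(
            "channel_labels",
            data=np.array(recording.channel_labels, dtype="S8"),
        )
    if events_path is None:
        events_path = path.with_name(path.stem + "_events.tsv")
    write_events_tsv(recording.schedule, events_path)


def load_recording(path, events_path=None) -> Recording:
    path = Path(path)
    if events_path is None:
        events_path = path.with_name(path.stem + "_events.tsv")
    schedule = read_events_tsv(events_path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        rate = float(f.attrs["rate_hz"])
        labels = tuple(s.decode() for s in f["channel_labels"][()])
    return Recording(data=data, rate_hz=rate, channel_labels=labels,
                     schedule=schedule)


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("is_target", data=epochs.is_target.astype(bool))
        f.attrs["rate_hz"] = epochs.rate_hz
        f.attrs["downsampled"] = epochs.downsampled
        f.create_dataset("channel_labels",
                         data=np.array(epochs.channel_labels, dtype="S8"))
        g = f.create_group("meta")
        for col in epochs.meta.columns:
            g.create_dataset(col, data=epochs.meta[col].to_numpy())


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        is_target = f["is_target"][()].astype(bool)
        rate = float(f.attrs["rate_hz"])
        downsampled = bool(f.attrs["downsampled"])
        labels = tuple(s.decode() for s in f["channel_labels"][()])
        meta = pd.DataFrame({col: f["meta"][col][()]
                             for col in f["meta"].keys()})
    order = ["participant", "soa_s", "block", "trial", "subtrial",
             "direction_deg", "onset_s", "sample_start"]
    meta = meta[[c for c in order if c in meta.columns]]
    return EpochSet(data=data, is_target=is_target, meta=meta, rate_hz=rate,
                    channel_labels=labels, downsampled=downsampled)
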