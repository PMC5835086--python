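"""Band-pass filtering, epoching, baseline correction and decimation.

The continuous recording is band-passed 0.1-8 Hz (zero-phase, 4th-order
Butterworth applied forward-backward), cut into 1,000-ms epochs locked to
every sub-trial onset, baseline-corrected by subtracting the mean of the
last 100 ms before onset, and downsampled by averaging every 10 samples
(256 samples -> 25 bins, the trailing 6 samples dropped). Flattened
channels x bins epochs are the classifier's feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import EdgeEpochError, InvalidFilterError, InvalidLengthError
from .simulate import Recording

EPOCH_S = 1.0
BASELINE_S = 0.1


@dataclass
class EpochSet:
    """Per-sub-trial EEG windows with labels and metadata.

    ``data`` is (n_epochs, n_channels, n_samples): 256 samples at 256 Hz
    when raw, 25 bins after decimation. ``meta`` carries one row per epoch
    (participant, soa_s, block, trial, subtrial, direction_deg, onset_s,
    sample_start).
    """

    data: np.ndarray
    is_target: np.ndarray
    meta: pd.DataFrame
    rate_hz: float
    channel_labels: tuple[str, ...]
    downsampled: bool = False

    def __post_init__(self) -> None:
        if len(self.is_target) != self.data.shape[0]:
            raise ValueError("labels length must equal number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


def bandpass(recording: Recording, low_hz: float = 0.1,
             high_hz: float = 8.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    Removes DC and attenuates energy above ``high_hz``; applied
    forward-backward (`sosfiltfilt`) so no phase delay shifts ERP
    latencies. Raises :class:`InvalidFilterError` for cutoffs outside
    (0, Nyquist).
    """
    nyq = recording.rate_hz / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise InvalidFilterError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass",
                 fs=recording.rate_hz, output="sos")
    # The 0.1-Hz edge has a multi-second transient: pad several of its
    # time constants so boundary effects never reach the data.
    padlen = min(recording.n_samples - 1,
                 int(6.0 / low_hz * recording.rate_hz))
    filtered = sosfiltfilt(sos, recording.data, axis=-1, padlen=padlen)
    return Recording(data=filtered, rate_hz=recording.rate_hz,
                     channel_labels=recording.channel_labels,
                     schedule=recording.schedule)


def epoch(recording: Recording, *, participant: int = 0,
          pre_samples: int | None = None) -> EpochSet:
    """Cut one 1,000-ms epoch per sub-trial event, [onset, onset + 1 s).

    Epochs at short SOA overlap and are extracted independently (shared
    samples are duplicated). Raises :class:`EdgeEpochError`, naming the
    event, if the window or the 100-ms pre-stimulus margin falls outside
    the recording.
    """
    fs = recording.rate_hz
    n_epoch = int(round(EPOCH_S * fs))
    if pre_samples is None:
        pre_samples = int(np.ceil(BASELINE_S * fs))  # 26 samples at 256 Hz
    rows = []
    starts = []
    for e in recording.schedule.events:
        start = int(round(e.onset_s * fs))
        if start - pre_samples < 0 or start + n_epoch > recording.n_samples:
            raise EdgeEpochError(
                f"event block={e.block_idx} trial={e.trial_idx} "
                f"subtrial={e.subtrial_idx} at {e.onset_s:.3f}s too close to "
                "recording edge"
            )
        starts.append(start)
        rows.append(
            (participant, recording.schedule.soa_s, e.block_idx, e.trial_idx,
             e.subtrial_idx, e.direction_deg, e.onset_s, start, e.is_target)
        )
    meta = pd.DataFrame(
        rows, columns=["participant", "soa_s", "block", "trial", "subtrial",
                       "direction_deg", "onset_s", "sample_start", "is_target"]
    )
    idx = np.asarray(starts)[:, None] + np.arange(n_epoch)[None, :]
    data = recording.data[:, idx].transpose(1, 0, 2).copy()
    return EpochSet(data=data, is_target=meta.is_target.to_numpy(),
                    meta=meta.drop(columns="is_target"),
                    rate_hz=fs, channel_labels=recording.channel_labels)


def baseline_correct(epochs: EpochSet, recording: Recording,
                     *, pre_samples: int | None = None) -> EpochSet:
    """Subtract the mean of the pre-stimulus window [onset - 100 ms, onset).

    The window is the ``pre_samples`` (default 26 at 256 Hz) samples
    immediately before each epoch's first sample, per channel.
    """
    if epochs.downsampled:
        raise ValueError("baseline correction applies to raw epochs")
    fs = recording.rate_hz
    if pre_samples is None:
        pre_samples = int(np.ceil(BASELINE_S * fs))
    starts = epochs.meta.sample_start.to_numpy()
    if np.any(starts - pre_samples < 0):
        raise EdgeEpochError("missing pre-stimulus data for baseline window")
    idx = starts[:, None] + np.arange(-pre_samples, 0)[None, :]
    baseline = recording.data[:, idx].transpose(1, 0, 2).mean(axis=-1)
    return replace(epochs, data=epochs.data - baseline[:, :, None],
                   meta=epochs.meta.copy())


def downsample(epochs: EpochSet, factor: int = 10) -> EpochSet:
    """Average every ``factor`` samples; the trailing remainder is dropped.

    256 samples at factor 10 give 25 bins (bins k = mean of samples
    [10k, 10k+10)); the last 6 samples do not enter any bin.
    """
    n = epochs.data.shape[-1]
    if n < factor:
        raise InvalidLengthError(f"epoch length {n} < factor {factor}")
    n_bins = n // factor
    trimmed = epochs.data[..., : n_bins * factor]
    binned = trimmed.reshape(*trimmed.shape[:-1], n_bins, factor).mean(axis=-1)
    return replace(epochs, data=binned, rate_hz=epochs.rate_hz / factor,
                   meta=epochs.meta.copy(), downsampled=True)


def to_features(epochs: EpochSet) -> np.ndarray:
    """Flatten epochs channel-major into (n_epochs, n_channels * n_bins).

    Feature j = channel (j // n_bins), bin (j % n_bins). Requires
    downsampled epochs (the classifier's 64 x 25 = 1,600-dimensional
    input).
    """
    if not epochs.downsampled:
        raise ValueError("downsample epochs before feature extraction")
    return epochs.data.reshape(epochs.n_epochs, -1)


def unflatten_features(x: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of :func:`to_features` for one vector or a batch."""
    x = np.asarray(x)
    if x.ndim == 1:
        return x.reshape(n_channels, -1)
    return x.reshape(x.shape[0], n_channels, -1)


def concatenate_epochs(sets: list[EpochSet], *,
                       renumber_blocks: bool = True) -> EpochSet:
    """Concatenate epoch sets from one participant's session chunks.

    With ``renumber_blocks`` the block indices of successive chunks are
    offset so every (block, trial) pair stays unique.
    """
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    first = sets[0]
    metas = []
    offset = 0
    for s in sets:
        if s.downsampled != first.downsampled or s.rate_hz != first.rate_hz:
            raise ValueError("epoch sets are not homogeneous")
        m = s.meta.copy()
        if renumber_blocks:
            m["block"] = m["block"] + offset
            offset = int(m["block"].max()) + 1
        metas.append(m)
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        is_target=np.concatenate([s.is_target for s in sets]),
        meta=pd.concat(metas, ignore_index=True),
        rate_hz=first.rate_hz,
        channel_labels=first.channel_labels,
        downsampled=first.downsampled,
    )


def preprocess_recording(recording: Recording, *, participant: int = 0,
                         low_hz: float = 0.1, high_hz: float = 8.0) -> EpochSet:
    """Full preprocessing chain: band-pass -> epoch -> baseline -> decimate."""
    filtered = bandpass(recording, low_hz, high_hz)
    eps = epoch(filtered, participant=participant)
    eps = baseline_correct(eps, filtered)
    return downsample(eps)
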