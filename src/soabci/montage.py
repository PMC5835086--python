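"""64-channel 10-10 montage (BioSemi 64 cap) and parametric scalp maps.

Scalp topographies are expressed as plain per-channel gain vectors, so no
electrode-position geometry is needed anywhere in the pipeline.
"""

from __future__ import annotations

import numpy as np

# BioSemi 64-channel cap, A1-A32 then B1-B32, in 10-10 names.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

N_CHANNELS = len(CHANNELS_64)

_FRONTOCENTRAL_CORE = {"Fz", "FCz", "Cz", "FC1", "FC2"}
_FRONTOCENTRAL_NEAR = {"AFz", "F1", "F2", "F3", "F4", "FC3", "FC4", "C1", "C2", "Fpz"}
_CENTROPARIETAL_CORE = {"Pz", "CPz", "POz", "CP1", "CP2", "P1", "P2"}
_CENTROPARIETAL_NEAR = {"Cz", "CP3", "CP4", "P3", "P4", "PO3", "PO4", "C1", "C2", "Oz"}


def channel_index(label: str, channels: tuple[str, ...] = CHANNELS_64) -> int:
    """Index of a channel label in the montage."""
    return channels.index(label)


def scalp_map(kind: str, channels: tuple[str, ...] = CHANNELS_64,
              core_gain: float = 1.0, near_gain: float = 0.6,
              far_gain: float = 0.15) -> np.ndarray:
    """Per-channel gain vector for a named topography.

    Parameters
    ----------
    kind
        ``"frontal-central"`` (N100/P200-like) or ``"central-posterior"``
        (P300-like). ``"uniform"`` gives all ones.
    """
    if kind == "uniform":
        return np.ones(len(channels))
    if kind == "frontal-central":
        core, near = _FRONTOCENTRAL_CORE, _FRONTOCENTRAL_NEAR
    elif kind == "central-posterior":
        core, near = _CENTROPARIETAL_CORE, _CENTROPARIETAL_NEAR
    else:
        raise ValueError(f"unknown scalp map kind: {kind!r}")
    gains = np.full(len(channels), far_gain)
    for i, label in enumerate(channels):
        if label in core:
            gains[i] = core_gain
        elif label in near:
            gains[i] = near_gain
    return gains
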