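"""Shared fixtures: small schedules, recordings and epoch sets."""

import numpy as np
import pandas as pd
import pytest

from soabci import (
    EpochSet,
    ErpTemplateParams,
    NoiseParams,
    generate_schedule,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_schedule():
    """Two blocks of five trials at SOA 0.5 s (compressed block gap)."""
    return generate_schedule(0.5, 2, 5, seed=42, inter_block_gap_s=2.0)


@pytest.fixture(scope="session")
def noisy_recording(small_schedule):
    return simulate_recording(small_schedule, seed=7)


@pytest.fixture(scope="session")
def noiseless_recording(small_schedule):
    return simulate_recording(
        small_schedule, noise=NoiseParams(background_sd_uV=0.0), seed=7
    )


@pytest.fixture(scope="session")
def single_trial_schedule():
    """One block, one trial: exactly one target sub-trial."""
    return generate_schedule(1.1, 1, 1, seed=3, inter_block_gap_s=2.0)


def make_epochset(
    n_blocks=5,
    trials_per_block=6,
    n_channels=4,
    n_bins=25,
    target_offset=0.0,
    noise_sd=1.0,
    seed=0,
    soa_s=0.5,
):
    """Small synthetic downsampled EpochSet for decoder tests.

    Target epochs get a constant ``target_offset`` added to every feature,
    so separability is controlled directly without simulating EEG.
    """
    rng = np.random.default_rng(seed)
    sched = generate_schedule(soa_s, n_blocks, trials_per_block, seed=seed,
                              inter_block_gap_s=2.0)
    meta = sched.to_frame().rename(columns={"onset_s": "onset_s"})
    is_target = meta.pop("is_target").to_numpy()
    meta["participant"] = 0
    meta["soa_s"] = soa_s
    meta["sample_start"] = (meta.onset_s * 256).round().astype(int)
    n = len(meta)
    data = rng.normal(0.0, noise_sd, size=(n, n_channels, n_bins))
    data[is_target] += target_offset
    return EpochSet(
        data=data,
        is_target=is_target,
        meta=meta.reset_index(drop=True),
        rate_hz=25.6,
        channel_labels=tuple(f"ch{i}" for i in range(n_channels)),
        downsampled=True,
    )


@pytest.fixture()
def separable_epochs():
    return make_epochset(target_offset=5.0, noise_sd=0.5, seed=1)


@pytest.fixture()
def noise_epochs():
    return make_epochset(target_offset=0.0, noise_sd=1.0, seed=2)
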