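"""Synthetic continuous 64-channel EEG for oddball schedules.

The generative model is deliberately simple and fully linear: every
sub-trial adds smooth Gaussian-in-time component bumps (N100, P200, and on
targets a P300 plus a frontal target-specific P200 reduction) at fixed
latencies, scaled by a per-channel scalp gain vector; overlapping responses
at short SOAs superpose linearly; stationary background noise (AR(2) with
shared spatial mixing by default, approximating the 1/f EEG spectrum) is
added on top. P300 amplitude is attenuated at short SOAs through a monotone
gain map, emulating the refractory target-to-target-interval effect.

Default component amplitudes are artifact choices at physiologically
typical magnitudes (single-trial P300 of a few microvolts against ~8 uV of
band-limited background EEG); the study they emulate plots but never
tabulates per-SOA amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CHANNELS_64, scalp_map
from .oddball import StimulusSchedule

RATE_HZ = 256.0

# Gaussian sigma from full width at half maximum.
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ErpComponent:
    """One evoked component: a Gaussian bump in time times a scalp map."""

    name: str
    latency_s: float
    width_s: float           # full width at half maximum of the bump
    amplitude_uV: float      # signed peak amplitude at unit scalp gain
    scalp: np.ndarray        # per-channel gain
    target_only: bool = False
    soa_gated: bool = False  # multiplied by the SOA-dependent P300 gain

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("width_s must be positive")
        self.scalp = np.asarray(self.scalp, dtype=float)


@dataclass
class ErpTemplateParams:
    """The set of evoked components injected at every sub-trial.

    Defaults place N100 (negative) and P200 (positive) fronto-centrally on
    every sub-trial, and on targets only a central-posterior P300 at 375 ms
    plus a small frontal P200 reduction (the target-specific frontal
    negativity seen 150-300 ms post-stimulus).
    """

    components: list[ErpComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            self.components = default_components()

    def scaled(self, factor: float) -> "ErpTemplateParams":
        """All amplitudes multiplied by ``factor`` (0 gives pure noise)."""
        return ErpTemplateParams(
            [replace(c, amplitude_uV=c.amplitude_uV * factor, scalp=c.scalp.copy())
             for c in self.components]
        )


def default_components(n_channels: int = len(CHANNELS_64)) -> list[ErpComponent]:
    fc = scalp_map("frontal-central")[:n_channels]
    cp = scalp_map("central-posterior")[:n_channels]
    return [
        ErpComponent("N100", 0.098, 0.030, -3.0, fc),
        ErpComponent("P200", 0.203, 0.040, 4.0, fc),
        ErpComponent("P200_target_reduction", 0.203, 0.040, -1.5, fc,
                     target_only=True),
        ErpComponent("P300", 0.375, 0.120, 6.0, cp,
                     target_only=True, soa_gated=True),
    ]


@dataclass
class NoiseParams:
    """Background-noise model for the ongoing EEG."""

    background_sd_uV: float = 8.0
    spectral_model: str = "autoregressive"  # pink | autoregressive | white
    ar_coefficients: tuple[float, ...] = (1.45, -0.55)
    channel_correlation: float = 0.3

    def __post_init__(self) -> None:
        if self.background_sd_uV < 0:
            raise ValueError("background_sd_uV must be >= 0")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise ValueError("channel_correlation must be in [0, 1]")
        if self.spectral_model not in {"pink", "autoregressive", "white"}:
            raise ValueError(f"unknown spectral model {self.spectral_model!r}")


@dataclass
class SoaAttenuation:
    """Monotone SOA -> P300 gain map in [0, 1].

    Defaults: full amplitude for SOA >= 0.4 s, 0.6 at 0.3 s, 0.3 at 0.2 s
    (linear interpolation in between), encoding the qualitative finding
    that short target-to-target intervals shrink the P300.
    """

    soa_points_s: tuple[float, ...] = (0.2, 0.3, 0.4)
    gains: tuple[float, ...] = (0.3, 0.6, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, float)
        if np.any((g < 0) | (g > 1)):
            raise ValueError("gains must lie in [0, 1]")
        if np.any(np.diff(g) < 0) or np.any(np.diff(self.soa_points_s) <= 0):
            raise ValueError("gain map must be non-decreasing in SOA")

    def p300_gain(self, soa_s: float) -> float:
        return float(np.interp(soa_s, self.soa_points_s, self.gains))


@dataclass
class Recording:
    """Continuous multi-channel EEG with its embedded stimulus schedule."""

    data: np.ndarray            # (n_channels, n_samples), microvolts
    rate_hz: float
    channel_labels: tuple[str, ...]
    schedule: StimulusSchedule

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def _bump(latency_s: float, width_s: float, rate_hz: float) -> tuple[np.ndarray, int]:
    """Sampled Gaussian bump and the sample offset of its first sample
    relative to stimulus onset. Support is +/- 4 sigma around the peak."""
    sigma = width_s * _FWHM_TO_SIGMA
    half = int(np.ceil(4 * sigma * rate_hz))
    peak = int(round(latency_s * rate_hz))
    k = np.arange(peak - half, peak + half + 1)
    t = k / rate_hz
    return np.exp(-0.5 * ((t - latency_s) / sigma) ** 2), peak - half


def _background_noise(n_channels: int, n_samples: int, noise: NoiseParams,
                      rng: np.random.Generator) -> np.ndarray:
    if noise.background_sd_uV == 0:
        return np.zeros((n_channels, n_samples))
    c = noise.channel_correlation
    # Shared + independent innovations give pairwise correlation c.
    indep = rng.standard_normal((n_channels, n_samples))
    if c > 0:
        common = rng.standard_normal(n_samples)
        white = np.sqrt(1 - c) * indep + np.sqrt(c) * common
    else:
        white = indep
    if noise.spectral_model == "white":
        shaped = white
    elif noise.spectral_model == "autoregressive":
        from scipy.signal import lfilter
        a1, a2 = noise.ar_coefficients
        shaped = lfilter([1.0], [1.0, -a1, -a2], white, axis=-1)
        shaped /= shaped.std(axis=-1, keepdims=True)
    else:  # pink: 1/sqrt(f) spectral shaping via FFT
        spec = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(n_samples)
        f[0] = f[1]
        spec /= np.sqrt(f)
        shaped = np.fft.irfft(spec, n=n_samples, axis=-1)
        shaped /= shaped.std(axis=-1, keepdims=True)
    return noise.background_sd_uV * shaped


def simulate_recording(
    schedule: StimulusSchedule,
    erp: ErpTemplateParams | None = None,
    noise: NoiseParams | None = None,
    atten: SoaAttenuation | None = None,
    seed: int = 0,
    *,
    channel_labels: tuple[str, ...] = CHANNELS_64,
    rate_hz: float = RATE_HZ,
    tail_s: float = 1.5,
) -> Recording:
    """Render a schedule into continuous EEG: noise + linear ERP superposition.

    Deterministic given ``seed``. P300-like (``soa_gated``) components are
    multiplied by the attenuation gain at the schedule's SOA and added only
    on target sub-trials.
    """
    erp = erp if erp is not None else ErpTemplateParams()
    noise = noise if noise is not None else NoiseParams()
    atten = atten if atten is not None else SoaAttenuation()
    n_ch = len(channel_labels)
    n_samples = int(np.ceil((schedule.events[-1].onset_s + tail_s) * rate_hz))
    rng = np.random.default_rng(seed)
    data = _background_noise(n_ch, n_samples, noise, rng)

    gain_soa = atten.p300_gain(schedule.soa_s)
    onset_samples = np.array(
        [int(round(e.onset_s * rate_hz)) for e in schedule.events]
    )
    is_target = np.array([e.is_target for e in schedule.events])
    for comp in erp.components:
        if comp.amplitude_uV == 0:
            continue
        bump, offset = _bump(comp.latency_s, comp.width_s, rate_hz)
        amp = comp.amplitude_uV * (gain_soa if comp.soa_gated else 1.0)
        profile = np.outer(comp.scalp[:n_ch], amp * bump)
        for k, start in enumerate(onset_samples + offset):
            if comp.target_only and not is_target[k]:
                continue
            stop = start + bump.size
            lo = max(start, 0)
            hi = min(stop, n_samples)
            if lo < hi:
                data[:, lo:hi] += profile[:, lo - start:hi - start]
    return Recording(data=data, rate_hz=rate_hz,
                     channel_labels=tuple(channel_labels), schedule=schedule)


def cohort_condition_seed(seed: int, participant: int, soa_index: int) -> int:
    """The per-(participant, condition) seed :func:`simulate_cohort` uses."""
    seq = np.random.SeedSequence(seed, spawn_key=(1, participant, soa_index))
    return int(seq.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_participants: int,
    soa_list: list[float],
    schedules: dict[float, StimulusSchedule] | None = None,
    erp: ErpTemplateParams | None = None,
    noise: NoiseParams | None = None,
    atten: SoaAttenuation | None = None,
    seed: int = 0,
    *,
    amplitude_lognorm_sd: float = 0.2,
    latency_jitter_sd_s: float = 0.015,
    schedule_kwargs: dict | None = None,
) -> list[tuple[int, float, Recording]]:
    """Simulate a cohort: participants x SOA conditions.

    Participant-level perturbations (multiplicative log-normal on component
    amplitudes, additive Gaussian on latencies) are drawn once per
    participant and shared across that participant's SOA conditions.
    If ``schedules`` is None, a fresh schedule is generated per
    (participant, SOA) with seeds split from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    erp = erp if erp is not None else ErpTemplateParams()
    out: list[tuple[int, float, Recording]] = []
    sched_kw = dict(schedule_kwargs or {})
    sched_kw.setdefault("n_blocks", 12)
    sched_kw.setdefault("trials_per_block", 30)
    # Simulated recordings compress the ~1-min rest between blocks: no task
    # events happen there and it only inflates memory.
    sched_kw.setdefault("inter_block_gap_s", 2.0)
    from .oddball import generate_schedule

    for p in range(n_participants):
        p_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, p)))
        n_comp = len(erp.components)
        amp_mult = (np.exp(p_rng.normal(0.0, amplitude_lognorm_sd, size=n_comp))
                    if amplitude_lognorm_sd > 0 else np.ones(n_comp))
        lat_shift = (p_rng.normal(0.0, latency_jitter_sd_s, size=n_comp)
                     if latency_jitter_sd_s > 0 else np.zeros(n_comp))
        p_erp = ErpTemplateParams(
            [replace(c, amplitude_uV=c.amplitude_uV * amp_mult[i],
                     latency_s=max(c.latency_s + lat_shift[i], 2 * c.width_s),
                     scalp=c.scalp.copy())
             for i, c in enumerate(erp.components)]
        )
        for j, soa in enumerate(soa_list):
            cond_seed = cohort_condition_seed(seed, p, j)
            if schedules is not None:
                sched = schedules[soa]
            else:
                sched = generate_schedule(soa, seed=cond_seed, **sched_kw)
            rec = simulate_recording(sched, p_erp, noise, atten, seed=cond_seed)
            out.append((p, soa, rec))
    return out
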