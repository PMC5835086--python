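"""Target-vs-non-target ERP statistics.

Per-participant class averages, paired t-test maps over time samples or
channels with Benjamini-Hochberg FDR correction, component latency
detection in the canonical N100/P200/P300 windows, and the Pearson
correlation between P300 amplitude and identification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientPairsError,
    MissingClassError,
    UndefinedCorrelationError,
)
from .preprocess import EpochSet

#: Component search windows in seconds (N100, P200, P300).
LATENCY_WINDOWS_S = {
    "n100": (0.080, 0.180),
    "p200": (0.170, 0.260),
    "p300": (0.300, 0.500),
}


@dataclass
class ErpAverage:
    """Per-participant class-mean waveforms, channels x samples."""

    participants: list[int]
    target_mean: np.ndarray      # (n_participants, n_channels, n_samples)
    nontarget_mean: np.ndarray
    n_target: np.ndarray         # epochs per class per participant
    n_nontarget: np.ndarray
    rate_hz: float
    channel_labels: tuple[str, ...]

    @property
    def grand_target(self) -> np.ndarray:
        """Unweighted mean of participant target means."""
        return self.target_mean.mean(axis=0)

    @property
    def grand_nontarget(self) -> np.ndarray:
        return self.nontarget_mean.mean(axis=0)

    @property
    def grand_difference(self) -> np.ndarray:
        return self.grand_target - self.grand_nontarget

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class StatMap:
    """Element-wise paired-test results with FDR and uncorrected masks.

    Zero-variance elements carry NaN t/p and are excluded from the FDR
    family (``m`` counts only defined p-values); their masks are False.
    """

    t_values: np.ndarray
    p_values: np.ndarray
    fdr_mask: np.ndarray
    uncorrected_mask: np.ndarray
    alpha: float
    m: int


@dataclass
class ComponentLatencies:
    """Detected peak latencies in seconds, one per component window."""

    n100_s: float
    p200_s: float
    p300_s: float


def grand_average(epochsets: list[EpochSet]) -> ErpAverage:
    """Average target and non-target epochs per participant.

    One :class:`EpochSet` per participant (same condition). Raises
    :class:`MissingClassError` if any participant lacks a class.
    """
    if not epochsets:
        raise ValueError("no epoch sets supplied")
    t_means, nt_means, n_t, n_nt, pids = [], [], [], [], []
    for eps in epochsets:
        tgt = eps.data[eps.is_target]
        ntg = eps.data[~eps.is_target]
        pid = int(eps.meta.participant.iloc[0])
        if tgt.shape[0] == 0 or ntg.shape[0] == 0:
            raise MissingClassError(f"participant {pid} lacks a class")
        t_means.append(tgt.mean(axis=0))
        nt_means.append(ntg.mean(axis=0))
        n_t.append(tgt.shape[0])
        n_nt.append(ntg.shape[0])
        pids.append(pid)
    first = epochsets[0]
    return ErpAverage(
        participants=pids,
        target_mean=np.stack(t_means),
        nontarget_mean=np.stack(nt_means),
        n_target=np.asarray(n_t),
        n_nontarget=np.asarray(n_nt),
        rate_hz=first.rate_hz,
        channel_labels=first.channel_labels,
    )


def paired_ttest_map(target: np.ndarray, nontarget: np.ndarray,
                     alpha: float = 0.05, q: float = 0.05) -> StatMap:
    """Element-wise two-sided paired t-test across participants (axis 0).

    ``target`` and ``nontarget`` are (n_participants, m) paired arrays; m
    may index time samples (time-course map) or channels (topography map).
    """
    target = np.asarray(target, float)
    nontarget = np.asarray(nontarget, float)
    if target.shape != nontarget.shape:
        raise ValueError("paired arrays must share a shape")
    n = target.shape[0]
    if n < 2:
        raise InsufficientPairsError("paired t-test needs >= 2 participants")
    d = target - nontarget
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    zero_var = sd == 0
    ok = ~zero_var
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    # Identical pairs everywhere: no evidence, not a degenerate family.
    exact_null = zero_var & (mean == 0)
    t[exact_null] = 0.0
    p[exact_null] = 1.0
    uncorrected = np.where(np.isnan(p), False, p < alpha)
    fdr = fdr_bh(p, q)
    m = int(np.sum(~np.isnan(p)))
    return StatMap(t_values=t, p_values=p, fdr_mask=fdr,
                   uncorrected_mask=uncorrected, alpha=alpha, m=m)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    Rejects H_(i) for all i <= k where k = max{i : p_(i) <= (i/m) q} on the
    sorted p-values. NaN entries are excluded from the family and never
    rejected. Raises on p outside [0, 1].
    """
    p = np.asarray(p_values, float)
    flat = p.ravel()
    defined = ~np.isnan(flat)
    if np.any((flat[defined] < 0) | (flat[defined] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(flat.shape, dtype=bool)
    if defined.sum() > 0:
        rej, *_ = multipletests(flat[defined], alpha=q, method="fdr_bh")
        mask[defined] = rej
    return mask.reshape(p.shape)


def find_latencies(erp_diff: np.ndarray, rate_hz: float) -> ComponentLatencies:
    """Peak latencies of a 0-1,000 ms difference wave at one channel.

    N100 is the minimum in 80-180 ms; P200 and P300 the maxima in
    170-260 ms and 300-500 ms respectively.
    """
    erp_diff = np.asarray(erp_diff, float)
    out = {}
    for name, (lo, hi) in LATENCY_WINDOWS_S.items():
        i0 = int(round(lo * rate_hz))
        i1 = int(round(hi * rate_hz)) + 1
        if i1 > erp_diff.size:
            raise ValueError(f"{name} window {lo}-{hi}s outside the waveform")
        seg = erp_diff[i0:i1]
        k = int(np.argmin(seg)) if name == "n100" else int(np.argmax(seg))
        out[name] = (i0 + k) / rate_hz
    return ComponentLatencies(n100_s=out["n100"], p200_s=out["p200"],
                              p300_s=out["p300"])


def correlate_amplitude_accuracy(amplitude: np.ndarray,
                                 accuracy: np.ndarray) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-condition P300 amplitude
    and identification accuracy."""
    amplitude = np.asarray(amplitude, float)
    accuracy = np.asarray(accuracy, float)
    if amplitude.shape != accuracy.shape or amplitude.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if amplitude.size < 3:
        raise ValueError("need at least 3 conditions")
    if np.std(amplitude) == 0 or np.std(accuracy) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r, p = stats.pearsonr(amplitude, accuracy)
    return float(r), float(p)
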