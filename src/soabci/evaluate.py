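"""Cross-validated 6-class target-direction identification and utility.

Trials (six sub-trials, one per direction) are split into five folds
stratified by target direction. Per fold the shrinkage lambda is chosen by
PSO on the training folds, an rFDA model is fitted, and held-out
sub-trials are scored. Identification averages scores over n consecutive
same-target trials per direction and takes the argmax; accuracy curves
feed the BCI-utility and Wolpaw information-transfer-rate formulas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FoldError, GroupingError
from .preprocess import EpochSet, to_features
from .rfda import FdaSolver, PsoConfig, pso_select_lambda, score

N_DIRECTIONS = 6


def _trial_table(epochs: EpochSet) -> pd.DataFrame:
    """One row per trial: block, trial, target direction."""
    meta = epochs.meta.copy()
    meta["is_target"] = epochs.is_target
    tgt = meta[meta.is_target]
    trials = tgt[["block", "trial", "direction_deg"]].rename(
        columns={"direction_deg": "target_direction_deg"}
    )
    counts = meta.groupby(["block", "trial"]).size()
    if not (counts == N_DIRECTIONS).all():
        raise ValueError("every trial must contain exactly 6 sub-trials")
    n_targets = meta.groupby(["block", "trial"]).is_target.sum()
    if not (n_targets == 1).all():
        raise ValueError("every trial must contain exactly one target")
    return trials.reset_index(drop=True)


def assign_folds(epochs: EpochSet, n_folds: int = 5,
                 seed: int = 0) -> pd.DataFrame:
    """Partition trials into folds, stratified by target direction.

    Within each target direction the trials are shuffled (seeded) and
    dealt round-robin, so every fold sees every direction as evenly as
    possible. Raises :class:`FoldError` if some direction has fewer
    trials than folds.
    """
    trials = _trial_table(epochs)
    rng = np.random.default_rng(seed)
    fold = np.full(len(trials), -1)
    cursor = 0  # rotate dealing across directions to balance fold sizes
    for _, grp in trials.groupby("target_direction_deg"):
        idx = grp.index.to_numpy()
        if idx.size < n_folds:
            raise FoldError(
                f"direction {grp.target_direction_deg.iloc[0]} has "
                f"{idx.size} trials < {n_folds} folds"
            )
        rng.shuffle(idx)
        fold[idx] = (cursor + np.arange(idx.size)) % n_folds
        cursor = (cursor + idx.size) % n_folds
    trials = trials.assign(fold=fold)
    return trials


def crossvalidate(epochs: EpochSet, pso_config: PsoConfig | None = None,
                  n_folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """5-fold cross-validated sub-trial scoring (the ScoreTable).

    Returns a frame with one row per sub-trial: fold, block, trial,
    direction_deg, score, is_target, target_direction_deg, plus the
    selected lambda per fold. Every sub-trial is scored exactly once, by a
    model whose training folds exclude its trial.
    """
    pso_config = pso_config if pso_config is not None else PsoConfig()
    trials = assign_folds(epochs, n_folds, seed)
    X = to_features(epochs)
    y = epochs.is_target.astype(bool)
    meta = epochs.meta
    key = list(zip(meta.block, meta.trial))
    trial_fold = {(b, t): f for b, t, f in
                  zip(trials.block, trials.trial, trials.fold)}
    trial_tgt = {(b, t): d for b, t, d in
                 zip(trials.block, trials.trial, trials.target_direction_deg)}
    epoch_fold = np.array([trial_fold[k] for k in key])

    rows = []
    for f in range(n_folds):
        test = epoch_fold == f
        train = ~test
        fold_seed = int(np.random.SeedSequence(
            pso_config.seed, spawn_key=(f,)).generate_state(1)[0] % (2**31))
        cfg = PsoConfig(
            n_particles=pso_config.n_particles,
            n_iterations=pso_config.n_iterations,
            inertia=pso_config.inertia,
            cognitive=pso_config.cognitive,
            social=pso_config.social,
            log10_lambda_bounds=pso_config.log10_lambda_bounds,
            inner_folds=pso_config.inner_folds,
            seed=fold_seed,
        )
        lam, _ = pso_select_lambda(X[train], y[train], cfg)
        model = FdaSolver(X[train], y[train]).model(lam)
        s = score(model, X[test])
        for i, idx in enumerate(np.flatnonzero(test)):
            b, t = key[idx]
            rows.append((f, b, t, int(meta.direction_deg.iloc[idx]),
                         float(s[i]), bool(y[idx]), trial_tgt[(b, t)], lam))
    return pd.DataFrame(rows, columns=[
        "fold", "block", "trial", "direction_deg", "score", "is_target",
        "target_direction_deg", "lambda",
    ])


def identify_target(scores: pd.DataFrame, n: int = 1,
                    seed: int = 0) -> pd.DataFrame:
    """n-trial-averaged 6-class identification.

    Within each (fold, target direction), trials are taken in (block,
    trial) order and grouped into disjoint consecutive sets of ``n``
    (remainder dropped). Per set, each direction's scores are averaged
    over the n trials and the argmax direction is the estimate. Argmax
    ties break by a seeded random preference order. Raises
    :class:`GroupingError` when no group can form anywhere.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pref = rng.permutation(N_DIRECTIONS)  # tie-break preference order
    rows = []
    for (fold, tgt), grp in scores.groupby(["fold", "target_direction_deg"]):
        pivot = grp.pivot_table(index=["block", "trial"],
                                columns="direction_deg", values="score")
        pivot = pivot.sort_index()
        dirs = pivot.columns.to_numpy()
        vals = pivot.to_numpy()
        n_sets = vals.shape[0] // n
        for s_i in range(n_sets):
            mean_scores = vals[s_i * n:(s_i + 1) * n].mean(axis=0)
            best = np.flatnonzero(mean_scores == mean_scores.max())
            if best.size > 1:
                choice = min(best, key=lambda i: pref[i % N_DIRECTIONS])
            else:
                choice = best[0]
            est = int(dirs[choice])
            rows.append((fold, int(tgt), s_i, est, est == int(tgt)))
    if not rows:
        raise GroupingError(f"no group of {n} trials available")
    return pd.DataFrame(rows, columns=["fold", "target_direction_deg",
                                       "set", "estimated_direction_deg",
                                       "correct"])


def accuracy_curve(scores: pd.DataFrame, n_max: int = 10,
                   seed: int = 0) -> pd.DataFrame:
    """Identification accuracy vs. number of averaged trials (1..n_max).

    ``accuracy_pct`` pools correct sets over folds; ``fold_mean_pct``
    averages per-fold accuracies unweighted. Points with zero sets are
    NaN-flagged rows, not errors.
    """
    rows = []
    for n in range(1, n_max + 1):
        try:
            sets = identify_target(scores, n=n, seed=seed)
        except GroupingError:
            rows.append((n, 0, 0, np.nan, np.nan))
            continue
        n_sets = len(sets)
        n_correct = int(sets.correct.sum())
        pooled = 100.0 * n_correct / n_sets
        fold_mean = 100.0 * sets.groupby("fold").correct.mean().mean()
        rows.append((n, n_sets, n_correct, pooled, fold_mean))
    return pd.DataFrame(rows, columns=["n", "n_sets", "n_correct",
                                       "accuracy_pct", "fold_mean_pct"])


def bci_utility(P: float, N: int = N_DIRECTIONS, n: int = 1,
                t: float = 1.1) -> float:
    """BCI utility in bits/minute.

    U = (2P/100 - 1) log2(N - 1) / c for P >= 50, else 0, with the
    selection duration c = n N t seconds converted to minutes. Utility
    accounts for error correction: below 50% accuracy corrections can
    never outpace errors, so the utility is zero.
    """
    P = float(P)
    if not 0.0 <= P <= 100.0:
        raise ValueError("P must be a percentage in [0, 100]")
    if N < 2 or n < 1 or t <= 0:
        raise ValueError("need N >= 2, n >= 1, t > 0")
    if P < 50.0:
        return 0.0
    c_min = n * N * t / 60.0
    return (2.0 * P / 100.0 - 1.0) * np.log2(N - 1) / c_min


def wolpaw_itr(P: float, N: int = N_DIRECTIONS, n: int = 1,
               t: float = 1.1) -> float:
    """Wolpaw information transfer rate in bits/minute.

    bits/selection = log2 N + p log2 p + (1-p) log2((1-p)/(N-1)) with
    p = P/100 and the 0 log 0 = 0 convention; divided by the selection
    duration c = n N t in minutes.
    """
    P = float(P)
    if not 0.0 <= P <= 100.0:
        raise ValueError("P must be a percentage in [0, 100]")
    if N < 2 or n < 1 or t <= 0:
        raise ValueError("need N >= 2, n >= 1, t > 0")
    p = P / 100.0
    bits = np.log2(N)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (N - 1))
    c_min = n * N * t / 60.0
    return max(bits, 0.0) / c_min


def utility_table(curve: pd.DataFrame, soa_s: float,
                  N: int = N_DIRECTIONS) -> pd.DataFrame:
    """Per-n BCI utility and ITR for one SOA's accuracy curve."""
    rows = []
    for r in curve.itertuples():
        if np.isnan(r.accuracy_pct):
            rows.append((soa_s, r.n, np.nan, np.nan))
            continue
        rows.append((soa_s, r.n,
                     bci_utility(r.accuracy_pct, N, r.n, soa_s),
                     wolpaw_itr(r.accuracy_pct, N, r.n, soa_s)))
    return pd.DataFrame(rows, columns=["soa_s", "n", "utility_bits_per_min",
                                       "itr_bits_per_min"])
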