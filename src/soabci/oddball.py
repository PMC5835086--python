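"""Oddball stimulus schedules and behavioral button-press scoring.

The experiment presents 100-ms white-noise bursts from six virtual sound
directions (30, -30, 90, -90, 150, -150 degrees). A *trial* is six
sub-trials covering every direction exactly once in pseudorandom order, so
each trial contains one target (the block's attended direction) and five
non-targets. Blocks fix the target direction; consecutive sub-trial onsets
within a block are separated by exactly one SOA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSoaError, UndefinedIntervalError

#: The six virtual sound-source azimuths, index 0..5.
DIRECTIONS_DEG: tuple[int, ...] = (30, -30, 90, -90, 150, -150)

SOUND_DURATION_S = 0.1

#: The eight stimulus-onset asynchronies studied, in seconds.
SOA_CONDITIONS_S: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.1)


def direction_index(angle_deg: int) -> int:
    """Map an azimuth in degrees to its direction index 0-5."""
    return DIRECTIONS_DEG.index(int(angle_deg))


@dataclass(frozen=True)
class SubTrialEvent:
    """One stimulus presentation."""

    onset_s: float
    direction_deg: int
    is_target: bool
    block_idx: int
    trial_idx: int
    subtrial_idx: int


@dataclass
class StimulusSchedule:
    """Complete oddball event list for one recording.

    Invariants: every trial's six directions are a permutation of all six;
    consecutive onsets within a block differ by exactly ``soa_s``; target
    directions are balanced over blocks when ``n_blocks`` is a multiple
    of six.
    """

    soa_s: float
    sound_duration_s: float
    events: list[SubTrialEvent]
    n_blocks: int
    trials_per_block: list[int]
    target_direction_per_block: list[int]  # degrees
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return int(sum(self.trials_per_block))

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration_s(self) -> float:
        """Time from origin to one second past the last onset."""
        return self.events[-1].onset_s + 1.0 if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "direction_deg": [e.direction_deg for e in self.events],
                "is_target": [e.is_target for e in self.events],
                "block": [e.block_idx for e in self.events],
                "trial": [e.trial_idx for e in self.events],
                "subtrial": [e.subtrial_idx for e in self.events],
            }
        )


@dataclass
class ButtonPressLog:
    """Sorted button-press timestamps sharing the schedule's time origin."""

    press_times_s: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.press_times_s, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("press times must be strictly increasing")


def generate_schedule(
    soa_s: float,
    n_blocks: int,
    trials_per_block: int | str = 30,
    seed: int = 0,
    *,
    inter_block_gap_s: float = 60.0,
    t_start_s: float = 1.0,
    avoid_boundary_adjacent_targets: bool = False,
) -> StimulusSchedule:
    """Generate a pseudorandom oddball schedule.

    Parameters
    ----------
    soa_s
        Stimulus onset asynchrony in seconds; must exceed the 100-ms sound.
    n_blocks
        Number of blocks; each block has one fixed target direction, and
        directions are balanced across blocks (exactly equal counts when
        ``n_blocks`` is a multiple of 6).
    trials_per_block
        An integer, or the string ``"30±1"`` to draw 29/30/31 uniformly per
        block from the seeded stream.
    seed
        The schedule is a pure function of all arguments including seed.
    inter_block_gap_s
        Silent gap between blocks (the recording pauses about a minute
        between blocks); never enters target-to-target statistics.
    t_start_s
        Onset of the first sub-trial, leaving a pre-stimulus margin for
        baseline estimation.
    avoid_boundary_adjacent_targets
        If True, resample a trial's permutation when its target would land
        in sub-trial 0 immediately after a previous trial's target in
        sub-trial 5 (back-to-back targets across the trial boundary).
        Off by default.
    """
    if soa_s <= SOUND_DURATION_S:
        raise InvalidSoaError(
            f"soa_s={soa_s} must exceed the sound duration {SOUND_DURATION_S} s"
        )
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(trials_per_block, str):
        if trials_per_block.replace(" ", "") not in {"30±1", "30+-1", "30+/-1"}:
            raise ValueError(f"unrecognized trials_per_block: {trials_per_block!r}")
        tpb = list(rng.integers(29, 32, size=n_blocks))
    else:
        tpb = [int(trials_per_block)] * n_blocks

    # Balanced target assignment: concatenated shuffled permutations of 0..5.
    pool: list[int] = []
    while len(pool) < n_blocks:
        pool.extend(rng.permutation(6).tolist())
    target_idx_per_block = pool[:n_blocks]

    events: list[SubTrialEvent] = []
    t0 = t_start_s
    for b in range(n_blocks):
        tgt_idx = target_idx_per_block[b]
        prev_target_pos = -1
        for tr in range(tpb[b]):
            perm = rng.permutation(6)
            if avoid_boundary_adjacent_targets:
                while prev_target_pos == 5 and int(np.argmax(perm == tgt_idx)) == 0:
                    perm = rng.permutation(6)
            for s in range(6):
                d_idx = int(perm[s])
                events.append(
                    SubTrialEvent(
                        onset_s=t0 + (tr * 6 + s) * soa_s,
                        direction_deg=DIRECTIONS_DEG[d_idx],
                        is_target=d_idx == tgt_idx,
                        block_idx=b,
                        trial_idx=tr,
                        subtrial_idx=s,
                    )
                )
            prev_target_pos = int(np.argmax(perm == tgt_idx))
        t0 += tpb[b] * 6 * soa_s + inter_block_gap_s

    return StimulusSchedule(
        soa_s=float(soa_s),
        sound_duration_s=SOUND_DURATION_S,
        events=events,
        n_blocks=n_blocks,
        trials_per_block=tpb,
        target_direction_per_block=[DIRECTIONS_DEG[i] for i in target_idx_per_block],
        seed=seed,
    )


def target_to_target_interval(schedule: StimulusSchedule) -> float:
    """Mean onset interval between consecutive targets, within blocks only.

    Cross-block pairs never contribute (the inter-block gap is task-free
    time). Raises :class:`UndefinedIntervalError` if no block has two
    targets.
    """
    intervals: list[float] = []
    df = schedule.to_frame()
    for _, blk in df[df.is_target].groupby("block"):
        onsets = blk.onset_s.to_numpy()
        if onsets.size >= 2:
            intervals.extend(np.diff(onsets))
    if not intervals:
        raise UndefinedIntervalError("fewer than 2 targets in every block")
    return float(np.mean(intervals))


def _response_windows(schedule: StimulusSchedule) -> list[tuple[float, float]]:
    """Scoring window per target: [onset+150 ms, next onset) for SOA >= 0.5 s,
    [onset+150 ms, onset+600 ms) for shorter SOAs."""
    windows = []
    events = schedule.events
    for i, e in enumerate(events):
        if not e.is_target:
            continue
        start = e.onset_s + 0.150
        if schedule.soa_s < 0.5:
            end = e.onset_s + 0.600
        else:
            nxt = events[i + 1] if i + 1 < len(events) else None
            if nxt is not None and nxt.block_idx == e.block_idx:
                end = nxt.onset_s
            else:  # last sub-trial of a block: allow one full SOA
                end = e.onset_s + schedule.soa_s
        windows.append((start, end))
    return windows


def score_button_presses(schedule: StimulusSchedule, log: ButtonPressLog) -> float:
    """Behavioral recognition accuracy: hit targets / all targets.

    A target is hit when at least one press falls in its response window;
    presses are assigned greedily, earliest window first, and each press
    may satisfy at most one target. An empty log gives accuracy 0.
    """
    windows = _response_windows(schedule)
    if not windows:
        raise ValueError("schedule contains no targets")
    presses = np.asarray(log.press_times_s, dtype=float)
    used = np.zeros(presses.size, dtype=bool)
    hits = 0
    for start, end in windows:
        idx = np.flatnonzero((presses >= start) & (presses < end) & ~used)
        if idx.size:
            used[idx[0]] = True
            hits += 1
    return hits / len(windows)


# ---------------------------------------------------------------------------
# BIDS-style events TSV serialization

_EVENT_COLUMNS = ["onset", "duration", "trial_type", "direction_deg",
                  "block", "trial", "subtrial"]


def write_events_tsv(schedule: StimulusSchedule, path) -> None:
    """Write the schedule as a BIDS-style events TSV."""
    df = pd.DataFrame(
        {
            "onset": [e.onset_s for e in schedule.events],
            "duration": schedule.sound_duration_s,
            "trial_type": ["target" if e.is_target else "nontarget"
                           for e in schedule.events],
            "direction_deg": [e.direction_deg for e in schedule.events],
            "block": [e.block_idx for e in schedule.events],
            "trial": [e.trial_idx for e in schedule.events],
            "subtrial": [e.subtrial_idx for e in schedule.events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> StimulusSchedule:
    """Reconstruct a :class:`StimulusSchedule` from an events TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events TSV missing columns: {sorted(missing)}")
    events = [
        SubTrialEvent(
            onset_s=float(r.onset),
            direction_deg=int(r.direction_deg),
            is_target=r.trial_type == "target",
            block_idx=int(r.block),
            trial_idx=int(r.trial),
            subtrial_idx=int(r.subtrial),
        )
        for r in df.itertuples()
    ]
    onsets = df.onset.to_numpy()
    same_block = df.block.to_numpy()[1:] == df.block.to_numpy()[:-1]
    diffs = np.diff(onsets)[same_block]
    soa = float(np.round(np.median(diffs), 6)) if diffs.size else float("nan")
    n_blocks = int(df.block.max()) + 1
    tpb = [int(df[df.block == b].trial.max()) + 1 for b in range(n_blocks)]
    tgt = [int(df[(df.block == b) & (df.trial_type == "target")]
               .direction_deg.iloc[0]) for b in range(n_blocks)]
    return StimulusSchedule(
        soa_s=soa,
        sound_duration_s=float(df.duration.iloc[0]),
        events=events,
        n_blocks=n_blocks,
        trials_per_block=tpb,
        target_direction_per_block=tgt,
        seed=None,
    )
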