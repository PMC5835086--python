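"""Study configuration and end-to-end orchestration.

A single YAML config drives the full replica study: per (participant, SOA)
condition the pipeline generates a schedule, simulates EEG, preprocesses,
cross-validates the rFDA decoder, and writes accuracy/utility tables plus
ERP statistics and a manifest with seeds and checksums. All stage seeds
are split deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

logger = logging.getLogger("soabci")

_STAGE_CODES = {"schedule": 0, "simulate": 1, "folds": 2, "pso": 3}


@dataclass
class StudyConfig:
    """Parameters of a full simulated study.

    Defaults are a scaled-down smoke configuration; the full replica uses
    9 participants, all eight SOAs and 12 blocks of 30 trials.
    """

    soa_list_s: list[float] = field(
        default_factory=lambda: [0.2, 0.5, 1.1])
    n_participants: int = 3
    n_blocks: int = 6
    trials_per_block: int = 12
    inter_block_gap_s: float = 2.0
    erp_amplitude_scale: float = 1.0
    noise_sd_uV: float = 8.0
    noise_model: str = "autoregressive"
    channel_correlation: float = 0.3
    attenuation_soa_points_s: list[float] = field(
        default_factory=lambda: [0.2, 0.3, 0.4])
    attenuation_gains: list[float] = field(
        default_factory=lambda: [0.3, 0.6, 1.0])
    pso_particles: int = 8
    pso_iterations: int = 10
    n_folds: int = 5
    n_max_averaged: int = 3
    master_seed: int = 1
    out_dir: str = "study_out"


_FIELDS = {f.name for f in dataclasses.fields(StudyConfig)}


def validate_config(config: StudyConfig) -> list[str]:
    """Return a list of validation error strings (empty = valid)."""
    errors = []
    from .oddball import SOUND_DURATION_S

    for soa in config.soa_list_s:
        if soa <= SOUND_DURATION_S:
            errors.append(f"soa_list_s: SOA {soa} <= sound duration 0.1 s")
    if config.n_participants < 1:
        errors.append("n_participants: must be >= 1")
    if config.n_blocks < 1:
        errors.append("n_blocks: must be >= 1")
    if config.trials_per_block < 1:
        errors.append("trials_per_block: must be >= 1")
    if config.noise_sd_uV < 0:
        errors.append("noise_sd_uV: must be >= 0")
    if config.noise_model not in {"pink", "autoregressive", "white"}:
        errors.append(f"noise_model: unknown model {config.noise_model!r}")
    if not 0 <= config.channel_correlation <= 1:
        errors.append("channel_correlation: must be in [0, 1]")
    gains = np.asarray(config.attenuation_gains, float)
    if np.any((gains < 0) | (gains > 1)) or np.any(np.diff(gains) < 0):
        errors.append("attenuation_gains: must be non-decreasing in [0, 1]")
    if config.pso_particles < 2:
        errors.append("pso_particles: must be >= 2")
    if config.n_max_averaged < 1:
        errors.append("n_max_averaged: must be >= 1")
    return errors


def load_config(path) -> StudyConfig:
    """Load a YAML config; unknown keys are rejected by name."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    config = StudyConfig(**raw)
    errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=False)


def stage_seed(master_seed: int, participant: int, condition: int,
               stage: str) -> int:
    """Counter-based per-(participant, condition, stage) seed below 2^31."""
    seq = np.random.SeedSequence(
        master_seed,
        spawn_key=(participant, condition, _STAGE_CODES[stage]),
    )
    return int(seq.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_study(config: StudyConfig, *, save_recordings: bool = False) -> Path:
    """Run the full pipeline for every (participant, SOA) condition.

    Writes per-condition events TSVs, score tables, accuracy and utility
    tables, per-SOA ERP statistics, and a manifest (seeds, artifact
    checksums). Deterministic given ``config.master_seed``. Returns the
    output directory.
    """
    from . import erpstats, evaluate, io, oddball, preprocess, simulate
    from .rfda import PsoConfig

    errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    erp = simulate.ErpTemplateParams().scaled(config.erp_amplitude_scale)
    noise = simulate.NoiseParams(
        background_sd_uV=config.noise_sd_uV,
        spectral_model=config.noise_model,
        channel_correlation=config.channel_correlation,
    )
    atten = simulate.SoaAttenuation(
        soa_points_s=tuple(config.attenuation_soa_points_s),
        gains=tuple(config.attenuation_gains),
    )
    manifest: dict = {"master_seed": config.master_seed, "seeds": {},
                      "artifacts": {}, "package_version": _version()}
    accuracy_rows, utility_rows = [], []
    epochsets_by_soa: dict[float, list] = {s: [] for s in config.soa_list_s}

    for ci, soa in enumerate(config.soa_list_s):
        for p in range(config.n_participants):
            tag = f"sub{p:02d}_soa{int(round(soa * 1000))}ms"
            logger.info("condition %s: scheduling", tag)
            s_sched = stage_seed(config.master_seed, p, ci, "schedule")
            s_sim = stage_seed(config.master_seed, p, ci, "simulate")
            s_folds = stage_seed(config.master_seed, p, ci, "folds")
            s_pso = stage_seed(config.master_seed, p, ci, "pso")
            manifest["seeds"][tag] = {
                "schedule": s_sched, "simulate": s_sim,
                "folds": s_folds, "pso": s_pso,
            }
            try:
                schedule = oddball.generate_schedule(
                    soa, config.n_blocks, config.trials_per_block,
                    seed=s_sched, inter_block_gap_s=config.inter_block_gap_s)
                events_path = out / f"{tag}_events.tsv"
                oddball.write_events_tsv(schedule, events_path)
                manifest["artifacts"][events_path.name] = _sha256(events_path)

                logger.info("condition %s: simulating", tag)
                rec = simulate.simulate_recording(
                    schedule, erp, noise, atten, seed=s_sim)
                if save_recordings:
                    rec_path = out / f"{tag}_rec.h5"
                    io.save_recording(rec, rec_path)
                    manifest["artifacts"][rec_path.name] = _sha256(rec_path)

                logger.info("condition %s: preprocessing", tag)
                eps = preprocess.preprocess_recording(rec, participant=p)
                epochsets_by_soa[soa].append(eps)

                logger.info("condition %s: decoding", tag)
                pso = PsoConfig(n_particles=config.pso_particles,
                                n_iterations=config.pso_iterations,
                                seed=s_pso)
                scores = evaluate.crossvalidate(
                    eps, pso, n_folds=config.n_folds, seed=s_folds)
                scores_path = out / f"{tag}_scores.tsv"
                scores.to_csv(scores_path, sep="\t", index=False)
                manifest["artifacts"][scores_path.name] = _sha256(scores_path)

                curve = evaluate.accuracy_curve(
                    scores, n_max=config.n_max_averaged, seed=s_folds)
                accuracy_rows.append(
                    curve.assign(participant=p, soa_s=soa))
                utility_rows.append(
                    evaluate.utility_table(curve, soa).assign(participant=p))
            except Exception as exc:
                raise RuntimeError(
                    f"stage failed for condition {tag}: {exc}") from exc

    acc = pd.concat(accuracy_rows, ignore_index=True)
    acc_path = out / "accuracy.tsv"
    acc.to_csv(acc_path, sep="\t", index=False)
    util = pd.concat(utility_rows, ignore_index=True)
    util_path = out / "utility.tsv"
    util.to_csv(util_path, sep="\t", index=False)
    manifest["artifacts"][acc_path.name] = _sha256(acc_path)
    manifest["artifacts"][util_path.name] = _sha256(util_path)

    # Per-SOA ERP statistics across participants (needs >= 2 participants).
    if config.n_participants >= 2:
        for soa, sets in epochsets_by_soa.items():
            avg = erpstats.grand_average(sets)
            pz = avg.channel_index("Pz")
            stat = erpstats.paired_ttest_map(
                avg.target_mean[:, pz, :], avg.nontarget_mean[:, pz, :])
            stats_path = out / f"erpstats_pz_soa{int(round(soa * 1000))}ms.tsv"
            pd.DataFrame({
                "bin": np.arange(stat.p_values.size),
                "t": stat.t_values,
                "p": stat.p_values,
                "fdr_significant": stat.fdr_mask,
                "uncorrected_significant": stat.uncorrected_mask,
            }).to_csv(stats_path, sep="\t", index=False)
            manifest["artifacts"][stats_path.name] = _sha256(stats_path)

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    logger.info("study complete: %s", out)
    return out


def _version() -> str:
    from . import __version__

    return __version__
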