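"""TSV and YAML I/O for session logs, cohorts, schedules, and configs.

All on-disk formats are plain text: tab-separated tables with headers, plus a
JSON manifest recording seeds and a config hash so any output can be traced
back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agent import AgentParams
from .cohort import CohortConfig, CohortDataset, ParticipantProfile
from .errors import ParseError, ValidationError
from .task import RewardSchedule, TaskConfig, TransitionStructure, TrialRecord

__all__ = [
    "write_session_log",
    "read_session_log",
    "write_schedule",
    "read_schedule",
    "write_cohort",
    "read_cohort",
    "save_config",
    "load_config",
    "config_hash",
]

SESSION_COLUMNS = [
    "trial",
    "phase",
    "choice1",
    "transition",
    "state2",
    "choice2",
    "reward",
    "prob_used",
]

PARTICIPANT_COLUMNS = [
    "id",
    "genotype",
    "group",
    "test_order",
    "mean_cycle_length",
    "estradiol_early",
    "estradiol_late",
]


def write_session_log(records, path) -> None:
    frame = pd.DataFrame(
        {
            "trial": [r.trial_index for r in records],
            "phase": [r.phase for r in records],
            "choice1": [r.choice1 for r in records],
            "transition": [r.transition for r in records],
            "state2": [r.state2 for r in records],
            "choice2": [r.choice2 for r in records],
            "reward": [r.reward for r in records],
            "prob_used": [repr(r.prob_used) for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_session_log(path, structure: TransitionStructure | None = None):
    """Read a session log TSV; validates schema and transition consistency.

    ``structure`` (when given) is used to check that every row's transition
    label agrees with its (choice1, state2) pair.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path} is empty or has no header") from None
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}", line=1)
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            rec = TrialRecord(
                trial_index=int(row.trial),
                phase=str(row.phase),
                choice1=str(row.choice1),
                transition=str(row.transition),
                state2=int(row.state2),
                choice2=str(row.choice2),
                reward=int(row.reward),
                prob_used=float(row.prob_used),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: {exc}", line=line) from None
        if structure is not None:
            try:
                rec.validate_transition(structure)
            except Exception as exc:
                raise ValidationError(f"{path}, line {line}: {exc}") from None
        records.append(rec)
    if not records:
        raise ParseError(f"{path}: no trial rows")
    return records


def write_schedule(schedule: RewardSchedule, path) -> None:
    frame = schedule.to_frame()
    frame["phase"] = frame["phase"].astype(str)
    for col in ("p_s1_a", "p_s1_b", "p_s2_a", "p_s2_b"):
        frame[col] = frame[col].map(repr)
    frame.to_csv(path, sep="\t", index=False)


def read_schedule(path) -> RewardSchedule:
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path} is empty or has no header") from None
    return RewardSchedule.from_frame(frame)


# ---------------------------------------------------------------------------
# cohort directories
# ---------------------------------------------------------------------------


def _session_filename(pid: str, cycle_phase: str) -> str:
    return f"trials_{pid}_{cycle_phase}.tsv"


def write_cohort(dataset: CohortDataset, outdir) -> None:
    """Write participants.tsv, per-session trial logs, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": p.id,
            "genotype": p.genotype,
            "group": p.genotype_group,
            "test_order": p.test_order,
            "mean_cycle_length": p.mean_cycle_length,
            "estradiol_early": p.estradiol_early,
            "estradiol_late": p.estradiol_late,
        }
        for p in dataset.participants
    ]
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS).to_csv(
        outdir / "participants.tsv", sep="\t", index=False
    )
    for (pid, cycle_phase), records in dataset.sessions.items():
        write_session_log(records, outdir / _session_filename(pid, cycle_phase))
    manifest = {
        "seed": dataset.seed,
        "n_participants": dataset.n_participants,
        "n_sessions": dataset.n_sessions,
        "config_hash": config_hash(dataset.config),
        "config": _cohort_config_to_dict(dataset.config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_cohort(indir) -> CohortDataset:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    config = _cohort_config_from_dict(manifest["config"])
    table = pd.read_csv(indir / "participants.tsv", sep="\t")
    participants = [
        ParticipantProfile(
            id=str(row.id),
            genotype=str(row.genotype),
            genotype_group=str(row.group),
            test_order=str(row.test_order),
            mean_cycle_length=float(row.mean_cycle_length),
            estradiol_early=float(row.estradiol_early),
            estradiol_late=float(row.estradiol_late),
        )
        for row in table.itertuples(index=False)
    ]
    sessions = {}
    for p in participants:
        for cycle_phase in ("early", "late"):
            sessions[(p.id, cycle_phase)] = read_session_log(
                indir / _session_filename(p.id, cycle_phase),
                structure=config.task.transition,
            )
    return CohortDataset(
        participants=participants,
        sessions=sessions,
        config=config,
        seed=manifest.get("seed"),
    )


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------


def _task_config_to_dict(cfg: TaskConfig) -> dict:
    return {
        "n_trials": cfg.n_trials,
        "n_drift": cfg.n_drift,
        "p_common": cfg.transition.p_common,
        "common_state": list(cfg.transition.common_state),
        "drift_bounds": list(cfg.drift_bounds),
        "drift_step_sd": cfg.drift_step_sd,
        "stable_probs": [list(p) for p in cfg.stable_probs],
        "seed": cfg.seed,
    }


def _task_config_from_dict(d: dict) -> TaskConfig:
    return TaskConfig(
        n_trials=d["n_trials"],
        n_drift=d["n_drift"],
        transition=TransitionStructure(
            p_common=d["p_common"], common_state=tuple(d["common_state"])
        ),
        drift_bounds=tuple(d["drift_bounds"]),
        drift_step_sd=d["drift_step_sd"],
        stable_probs=tuple(tuple(p) for p in d["stable_probs"]),
        seed=d.get("seed"),
    )


def _agent_params_to_dict(p: AgentParams) -> dict:
    return {
        k: getattr(p, k)
        for k in ("alpha1", "alpha2", "beta1", "beta2", "lam", "w", "persev")
    }


def _cohort_config_to_dict(cfg: CohortConfig) -> dict:
    return {
        "n_met_hom": cfg.n_met_hom,
        "n_val_carrier": cfg.n_val_carrier,
        "met_allele_freq": cfg.met_allele_freq,
        "n_early_first": cfg.n_early_first,
        "estradiol_summary": {
            f"{g}:{ph}": list(v) for (g, ph), v in cfg.estradiol_summary.items()
        },
        "estradiol_n_source": dict(cfg.estradiol_n_source),
        "cycle_length_summary": {g: list(v) for g, v in cfg.cycle_length_summary.items()},
        "base_params": _agent_params_to_dict(cfg.base_params),
        "effect_map": {
            f"{g}:{cp}:{tp}": dict(shifts)
            for (g, cp, tp), shifts in cfg.effect_map.items()
        },
        "task": _task_config_to_dict(cfg.task),
        "seed": cfg.seed,
    }


def _cohort_config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(
        n_met_hom=d["n_met_hom"],
        n_val_carrier=d["n_val_carrier"],
        met_allele_freq=d["met_allele_freq"],
        n_early_first=d["n_early_first"],
        estradiol_summary={
            tuple(k.split(":")): tuple(v) for k, v in d["estradiol_summary"].items()
        },
        estradiol_n_source=dict(d["estradiol_n_source"]),
        cycle_length_summary={g: tuple(v) for g, v in d["cycle_length_summary"].items()},
        base_params=AgentParams(**d["base_params"]),
        effect_map={
            tuple(k.split(":")): dict(v) for k, v in d["effect_map"].items()
        },
        task=_task_config_from_dict(d["task"]),
        seed=d.get("seed"),
    )


def save_config(config, path) -> None:
    """Serialize a cohort config (the full run specification) to YAML."""
    Path(path).write_text(
        yaml.safe_dump(_cohort_config_to_dict(config), sort_keys=True)
    )


def load_config(path) -> CohortConfig:
    return _cohort_config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config) -> str:
    """Stable hash of the canonical YAML form of a config."""
    canonical = yaml.safe_dump(_cohort_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
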