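"""Stay-frequency tabulation and the model-free / model-based learning scores.

A *stay* is a trial whose first-stage choice repeats the previous trial's
first-stage choice.  Each stay/switch observation is classified by the
*previous* trial's outcome (rewarded / unrewarded) and transition (common /
rare), yielding a 2x2 table of stay percentages per session-phase.  Two linear
contrasts on that table summarize behavior:

    model-free score  = %rewarded-common + %rewarded-rare
                      - %unrewarded-common - %unrewarded-rare
    model-based score = %rewarded-common + %unrewarded-rare
                      - %rewarded-rare  - %unrewarded-common

The model-free score is the main effect of previous reward (repeat what paid,
regardless of structure); the model-based score is the reward-by-transition
interaction (credit the first-stage option whose *common* destination paid).
Both live in percentage points, range [-200, 200].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedCellError

__all__ = [
    "CELLS",
    "StayTable",
    "LearningScores",
    "DeltaMetrics",
    "tabulate_stays",
    "tabulate_stays_arrays",
    "model_free_score",
    "model_based_score",
    "learning_scores",
    "delta_scores",
    "total_coins",
]

#: cell order used everywhere: (previous reward, previous transition)
CELLS = (
    "rewarded_common",
    "rewarded_rare",
    "unrewarded_common",
    "unrewarded_rare",
)


def _cell_name(rewarded: bool, common: bool) -> str:
    return ("rewarded_" if rewarded else "unrewarded_") + (
        "common" if common else "rare"
    )


@dataclass
class StayTable:
    """Stay counts and percentages in the 2x2 previous-reward x previous-transition grid."""

    n_stay: dict
    n_obs: dict
    phase: str | None = None
    session_id: str | None = None

    @property
    def stay_pct(self) -> dict:
        """Per-cell stay percentage; NaN where the cell has no observations."""
        return {
            c: (100.0 * self.n_stay[c] / self.n_obs[c] if self.n_obs[c] else np.nan)
            for c in CELLS
        }

    @property
    def undefined_cells(self) -> tuple:
        return tuple(c for c in CELLS if self.n_obs[c] == 0)

    @property
    def n_total(self) -> int:
        return sum(self.n_obs.values())

    def require_defined(self) -> None:
        missing = self.undefined_cells
        if missing:
            raise UndefinedCellError(missing)


@dataclass(frozen=True)
class LearningScores:
    model_free: float
    model_based: float
    phase: str | None = None
    session_id: str | None = None


@dataclass(frozen=True)
class DeltaMetrics:
    """Late-minus-early differences for one participant and task phase."""

    delta_model_free: float
    delta_model_based: float
    delta_coins: float | None = None
    participant: str | None = None
    task_phase: str | None = None


def tabulate_stays(records, phase: str | None = None) -> StayTable:
    """Tabulate stay observations from a time-ordered trial log.

    Trial ``t`` (t >= 2) contributes one observation: stay iff its first-stage
    choice equals trial ``t-1``'s, classified by trial ``t-1``'s reward and
    transition, and assigned to the phase of trial ``t`` itself (so the first
    stable trial, conditioning on the last drift trial, counts as stable).
    ``phase`` restricts the table to "drift" or "stable" observations; None
    keeps the whole session.
    """
    records = list(records)
    idx = [r.trial_index for r in records]
    if idx != sorted(idx) or len(set(idx)) != len(idx):
        raise InvalidInputError("session log must be time-ordered without duplicates")
    n_stay = {c: 0 for c in CELLS}
    n_obs = {c: 0 for c in CELLS}
    for prev, cur in zip(records, records[1:]):
        if phase is not None and cur.phase != phase:
            continue
        cell = _cell_name(prev.reward == 1, prev.transition == "common")
        n_obs[cell] += 1
        if cur.choice1 == prev.choice1:
            n_stay[cell] += 1
    return StayTable(n_stay=n_stay, n_obs=n_obs, phase=phase)


def tabulate_stays_arrays(
    choice1: np.ndarray,
    reward: np.ndarray,
    common: np.ndarray,
    trial_phase: np.ndarray,
    phase: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized stay tabulation over a batch of sessions.

    Arrays have shape ``(n_sessions, n_trials)``; ``trial_phase`` is the
    shared per-trial phase labeling.  Returns ``(n_stay, n_obs)`` arrays of
    shape ``(n_sessions, 4)`` in :data:`CELLS` order.
    """
    choice1 = np.asarray(choice1)
    stay = choice1[:, 1:] == choice1[:, :-1]
    prev_r = np.asarray(reward)[:, :-1].astype(bool)
    prev_c = np.asarray(common)[:, :-1]
    in_phase = np.asarray(trial_phase)[1:] == phase  # phase of the current trial
    masks = [
        prev_r & prev_c,
        prev_r & ~prev_c,
        ~prev_r & prev_c,
        ~prev_r & ~prev_c,
    ]
    n_stay = np.empty((choice1.shape[0], 4), dtype=np.int64)
    n_obs = np.empty_like(n_stay)
    for j, m in enumerate(masks):
        m = m & in_phase[None, :]
        n_obs[:, j] = m.sum(axis=1)
        n_stay[:, j] = (m & stay).sum(axis=1)
    return n_stay, n_obs


def model_free_score(table: StayTable) -> float:
    """Main effect of previous reward on stay percentages."""
    table.require_defined()
    p = table.stay_pct
    return (
        p["rewarded_common"]
        + p["rewarded_rare"]
        - p["unrewarded_common"]
        - p["unrewarded_rare"]
    )


def model_based_score(table: StayTable) -> float:
    """Previous reward x previous transition interaction on stay percentages."""
    table.require_defined()
    p = table.stay_pct
    return (
        p["rewarded_common"]
        + p["unrewarded_rare"]
        - p["rewarded_rare"]
        - p["unrewarded_common"]
    )


def learning_scores(table: StayTable) -> LearningScores:
    return LearningScores(
        model_free=model_free_score(table),
        model_based=model_based_score(table),
        phase=table.phase,
        session_id=table.session_id,
    )


def delta_scores(
    early: LearningScores,
    late: LearningScores,
    coins_early: float | None = None,
    coins_late: float | None = None,
    participant: str | None = None,
) -> DeltaMetrics:
    """Late-minus-early score differences for one participant/task phase."""
    if early.phase != late.phase:
        raise InvalidInputError(
            f"task phases differ: early={early.phase!r}, late={late.phase!r}"
        )
    delta_coins = None
    if coins_early is not None and coins_late is not None:
        delta_coins = coins_late - coins_early
    return DeltaMetrics(
        delta_model_free=late.model_free - early.model_free,
        delta_model_based=late.model_based - early.model_based,
        delta_coins=delta_coins,
        participant=participant,
        task_phase=early.phase,
    )


def total_coins(records, phase: str | None = None) -> int:
    """Number of rewarded trials (1 coin each), optionally within one phase."""
    return sum(
        r.reward for r in records if phase is None or r.phase == phase
    )
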