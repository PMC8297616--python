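"""Generative model of the two-step Markov decision task.

The task has two decision stages per trial.  A first-stage choice between two
options (``A``/``B``) leads probabilistically to one of two second-stage
states: each first-stage option has a *common* destination reached with
probability ``p_common`` (0.7 by default) and a *rare* destination reached
otherwise.  A second-stage choice (``a``/``b``) then pays a unit reward with a
probability given by the reward schedule.  Sessions run 300 trials: during the
first 150 (the *drift phase*) the four reward probabilities follow slow
reflected random walks inside [0.25, 0.75]; during the remaining 150 (the
*stable phase*) they are fixed at 0.7 vs 0.3 in state 1 and 0.6 vs 0.4 in
state 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "STAGE1_ACTIONS",
    "STAGE2_ACTIONS",
    "STATES",
    "PHASES",
    "TransitionStructure",
    "RewardSchedule",
    "TaskConfig",
    "TrialRecord",
    "build_drift_schedule",
    "build_stable_schedule",
    "concat_schedules",
    "sample_transition",
    "emit_reward",
    "phase_of_trial",
]

STAGE1_ACTIONS = ("A", "B")
STAGE2_ACTIONS = ("a", "b")
STATES = (1, 2)
PHASES = ("drift", "stable")

#: defaults for the task as run in the study
DEFAULT_P_COMMON = 0.7
DEFAULT_DRIFT_BOUNDS = (0.25, 0.75)
DEFAULT_DRIFT_STEP_SD = 0.025
DEFAULT_STABLE_PROBS = ((0.7, 0.3), (0.6, 0.4))


def _as_action_index(choice1) -> int:
    if choice1 in (0, 1):
        return int(choice1)
    if choice1 in STAGE1_ACTIONS:
        return STAGE1_ACTIONS.index(choice1)
    raise InvalidInputError(f"unknown first-stage action: {choice1!r}")


@dataclass(frozen=True)
class TransitionStructure:
    """First-stage → second-stage transition rule.

    ``common_state[i]`` is the 0-based index of the second-stage state that
    first-stage action ``i`` reaches on a common transition.  The two actions
    must have distinct common destinations so the mapping is informative.
    """

    p_common: float = DEFAULT_P_COMMON
    common_state: tuple[int, int] = (0, 1)

    def __post_init__(self):
        if not 0.5 < self.p_common < 1.0:
            raise InvalidConfigError(
                f"p_common must lie in (0.5, 1); got {self.p_common}"
            )
        if sorted(self.common_state) != [0, 1]:
            raise InvalidConfigError(
                "the two first-stage actions must have distinct common "
                f"destinations; got {self.common_state}"
            )

    @property
    def p_rare(self) -> float:
        return 1.0 - self.p_common

    def common_destination(self, choice1) -> int:
        return self.common_state[_as_action_index(choice1)]

    def rare_destination(self, choice1) -> int:
        return 1 - self.common_destination(choice1)

    def label(self, choice1, state_index: int) -> str:
        """Transition label implied by a (first-stage choice, state) pair."""
        return "common" if state_index == self.common_destination(choice1) else "rare"


@dataclass
class RewardSchedule:
    """Per-trial reward probabilities, shape ``(n_trials, 2 states, 2 actions)``."""

    probs: np.ndarray
    phase: np.ndarray  # per-trial label, "drift" or "stable"
    bounds: tuple[float, float] | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.probs.ndim != 3 or self.probs.shape[1:] != (2, 2):
            raise InvalidConfigError(
                f"schedule must have shape (n_trials, 2, 2); got {self.probs.shape}"
            )
        if len(self.phase) != len(self.probs):
            raise InvalidConfigError("phase labels must match n_trials")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise InvalidConfigError("reward probabilities must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return len(self.probs)

    def prob(self, trial_index: int, state_index: int, action_index: int) -> float:
        if not 1 <= trial_index <= self.n_trials:
            raise InvalidInputError(
                f"trial_index {trial_index} outside schedule of {self.n_trials} trials"
            )
        return float(self.probs[trial_index - 1, state_index, action_index])

    def to_frame(self) -> pd.DataFrame:
        """TSV-friendly layout: trial, phase, p_s1_a, p_s1_b, p_s2_a, p_s2_b."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "phase": self.phase,
                "p_s1_a": self.probs[:, 0, 0],
                "p_s1_b": self.probs[:, 0, 1],
                "p_s2_a": self.probs[:, 1, 0],
                "p_s2_b": self.probs[:, 1, 1],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RewardSchedule":
        cols = ["p_s1_a", "p_s1_b", "p_s2_a", "p_s2_b"]
        probs = frame[cols].to_numpy(dtype=float).reshape(-1, 2, 2)
        return cls(probs=probs, phase=frame["phase"].to_numpy(dtype=object))


def _reflect(x: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Fold values back into [lower, upper] (reflecting boundary)."""
    width = upper - lower
    y = np.mod(x - lower, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return y + lower


def build_drift_schedule(
    n_trials: int = 150,
    bounds: tuple[float, float] = DEFAULT_DRIFT_BOUNDS,
    step_sd: float = DEFAULT_DRIFT_STEP_SD,
    seed=None,
) -> RewardSchedule:
    """Drift-phase schedule: four independent reflected Gaussian random walks.

    Each of the four (state, action) reward probabilities starts uniformly
    inside ``bounds`` and takes Gaussian steps of standard deviation
    ``step_sd`` every trial, reflected at the bounds so the probability never
    leaves the interval.  ``seed`` may be an int or a ``numpy`` Generator.
    """
    if n_trials <= 0:
        raise InvalidConfigError(f"n_trials must be positive; got {n_trials}")
    lower, upper = bounds
    if not (0.0 <= lower < upper <= 1.0):
        raise InvalidConfigError(f"bounds must satisfy 0 <= lower < upper <= 1; got {bounds}")
    if step_sd < 0:
        raise InvalidConfigError(f"step_sd must be non-negative; got {step_sd}")
    rng = np.random.default_rng(seed)
    probs = np.empty((n_trials, 2, 2))
    probs[0] = rng.uniform(lower, upper, size=(2, 2))
    for t in range(1, n_trials):
        step = rng.normal(0.0, step_sd, size=(2, 2)) if step_sd > 0 else 0.0
        probs[t] = _reflect(probs[t - 1] + step, lower, upper)
    return RewardSchedule(
        probs=probs,
        phase=np.array(["drift"] * n_trials, dtype=object),
        bounds=(lower, upper),
    )


def build_stable_schedule(
    n_trials: int = 150,
    final_probs=DEFAULT_STABLE_PROBS,
) -> RewardSchedule:
    """Stable-phase schedule: reward probabilities constant across trials."""
    if n_trials <= 0:
        raise InvalidConfigError(f"n_trials must be positive; got {n_trials}")
    arr = np.asarray(final_probs, dtype=float)
    if arr.shape != (2, 2):
        raise InvalidConfigError(
            f"final_probs must be a pair of per-state probability pairs; got {final_probs}"
        )
    if np.any(arr < 0) or np.any(arr > 1):
        raise InvalidConfigError("final_probs must lie in [0, 1]")
    probs = np.broadcast_to(arr, (n_trials, 2, 2)).copy()
    return RewardSchedule(
        probs=probs, phase=np.array(["stable"] * n_trials, dtype=object)
    )


def concat_schedules(first: RewardSchedule, second: RewardSchedule) -> RewardSchedule:
    return RewardSchedule(
        probs=np.concatenate([first.probs, second.probs]),
        phase=np.concatenate([first.phase, second.phase]),
        bounds=first.bounds,
    )


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters (defaults reproduce the study design)."""

    n_trials: int = 300
    n_drift: int = 150
    transition: TransitionStructure = field(default_factory=TransitionStructure)
    drift_bounds: tuple[float, float] = DEFAULT_DRIFT_BOUNDS
    drift_step_sd: float = DEFAULT_DRIFT_STEP_SD
    stable_probs: tuple = DEFAULT_STABLE_PROBS
    seed: int | None = None

    def __post_init__(self):
        if self.n_trials <= 0:
            raise InvalidConfigError(f"n_trials must be positive; got {self.n_trials}")
        if not 0 <= self.n_drift <= self.n_trials:
            raise InvalidConfigError(
                f"n_drift must lie in [0, n_trials]; got {self.n_drift}"
            )

    @property
    def n_stable(self) -> int:
        return self.n_trials - self.n_drift

    def build_schedule(self, seed=None) -> RewardSchedule:
        """Full session schedule: drift walks followed by the stable block."""
        if seed is None:
            seed = self.seed
        parts = []
        if self.n_drift > 0:
            parts.append(
                build_drift_schedule(
                    self.n_drift, self.drift_bounds, self.drift_step_sd, seed
                )
            )
        if self.n_stable > 0:
            parts.append(build_stable_schedule(self.n_stable, self.stable_probs))
        sched = parts[0]
        for part in parts[1:]:
            sched = concat_schedules(sched, part)
        return sched

    def replace(self, **kwargs) -> "TaskConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialRecord:
    """One completed task trial.

    ``state2`` is 1-based (1 or 2) to match the on-disk log format;
    ``prob_used`` records the scheduled probability that generated the reward
    so logs can be audited against their schedule.
    """

    trial_index: int
    phase: str
    choice1: str
    transition: str
    state2: int
    choice2: str
    reward: int
    prob_used: float

    def __post_init__(self):
        if self.choice1 not in STAGE1_ACTIONS:
            raise InvalidInputError(f"choice1 must be A or B; got {self.choice1!r}")
        if self.choice2 not in STAGE2_ACTIONS:
            raise InvalidInputError(f"choice2 must be a or b; got {self.choice2!r}")
        if self.state2 not in STATES:
            raise InvalidInputError(f"state2 must be 1 or 2; got {self.state2!r}")
        if self.transition not in ("common", "rare"):
            raise InvalidInputError(f"bad transition label: {self.transition!r}")
        if self.reward not in (0, 1):
            raise InvalidInputError(f"reward must be 0 or 1; got {self.reward!r}")
        if self.phase not in PHASES:
            raise InvalidInputError(f"phase must be drift or stable; got {self.phase!r}")

    def validate_transition(self, structure: TransitionStructure) -> None:
        expected = structure.label(self.choice1, self.state2 - 1)
        if expected != self.transition:
            raise InvalidInputError(
                f"trial {self.trial_index}: transition labeled {self.transition!r} "
                f"but choice {self.choice1}→state {self.state2} is {expected!r} "
                "under the transition structure"
            )


def phase_of_trial(trial_index: int, config: TaskConfig) -> str:
    """Phase of a 1-based trial index: drift iff ``trial_index <= n_drift``."""
    if not 1 <= trial_index <= config.n_trials:
        raise InvalidInputError(
            f"trial_index must lie in [1, {config.n_trials}]; got {trial_index}"
        )
    return "drift" if trial_index <= config.n_drift else "stable"


def sample_transition(choice1, structure: TransitionStructure, rng) -> tuple[int, str]:
    """Sample the second-stage state for a first-stage choice.

    Returns ``(state2, label)`` with ``state2`` 1-based.  The common
    destination is reached with probability ``p_common``.
    """
    a = _as_action_index(choice1)
    common = structure.common_state[a]
    if rng.random() < structure.p_common:
        return common + 1, "common"
    return (1 - common) + 1, "rare"


def emit_reward(
    schedule: RewardSchedule, trial_index: int, state2, choice2, rng
) -> tuple[int, float]:
    """Bernoulli reward draw for a second-stage choice.

    ``state2`` may be 1-based (1/2) or a 0-based index; ``choice2`` may be
    "a"/"b" or 0/1.  Returns ``(reward, prob_used)``.
    """
    if state2 in STATES:
        s = int(state2) - 1
    elif state2 in (0, 1):
        s = int(state2)
    else:
        raise InvalidInputError(f"unknown state: {state2!r}")
    if choice2 in STAGE2_ACTIONS:
        c = STAGE2_ACTIONS.index(choice2)
    elif choice2 in (0, 1):
        c = int(choice2)
    else:
        raise InvalidInputError(f"unknown second-stage action: {choice2!r}")
    p = schedule.prob(trial_index, s, c)
    return int(rng.random() < p), p
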