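"""Hybrid model-free / model-based agent for the two-step task.

The agent is the standard dual-controller architecture used throughout the
two-step literature.  Second-stage action values ``Q2`` are learned by simple
delta-rule updates.  First-stage values mix a model-free estimate ``Q_MF``
(updated toward the pre-update second-stage value, plus an
eligibility-weighted share of the final reward prediction error — so with
eligibility ``lam = 1`` the update reduces to a pure delta rule on reward)
with a model-based estimate ``Q_MB`` that plans through the known transition
probabilities:

    Q_MB(a) = p_common * max_b Q2(s_common(a), b)
            + (1 - p_common) * max_b Q2(s_rare(a), b)

First-stage choice is softmax over ``beta1 * (w*Q_MB + (1-w)*Q_MF)`` plus a
perseveration bonus for repeating the previous first-stage choice; ``w`` in
[0, 1] is the model-based weight.  Second-stage choice is softmax over
``beta2 * Q2``.  A session may use different parameter sets in the drift and
stable phases (the switch happens exactly at the phase boundary); Q-values
carry over.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidConfigError
from .task import (
    STAGE1_ACTIONS,
    STAGE2_ACTIONS,
    RewardSchedule,
    TaskConfig,
    TrialRecord,
)

__all__ = ["AgentParams", "simulate_session", "simulate_sessions_batch"]


@dataclass(frozen=True)
class AgentParams:
    """Hybrid-agent parameters.

    alpha1, alpha2 : first/second-stage learning rates in [0, 1]
    beta1, beta2   : softmax inverse temperatures, >= 0
    lam            : eligibility-trace weight in [0, 1]
    w              : model-based weight in [0, 1] (0 = pure model-free)
    persev         : additive bonus for repeating the previous stage-1 choice
    """

    alpha1: float = 0.5
    alpha2: float = 0.5
    beta1: float = 4.0
    beta2: float = 2.5
    lam: float = 0.6
    w: float = 0.6
    persev: float = 1.0

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]; got {v}")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidConfigError(f"{name} must be non-negative; got {v}")

    def shifted(self, **shifts) -> "AgentParams":
        """Return a copy with additive shifts, clipped to the legal range."""
        new = {}
        for name, delta in shifts.items():
            v = getattr(self, name) + delta
            if name in ("alpha1", "alpha2", "lam", "w"):
                v = min(1.0, max(0.0, v))
            elif name in ("beta1", "beta2"):
                v = max(0.0, v)
            new[name] = v
        return replace(self, **new)


def _softmax2(pref0: float, pref1: float) -> float:
    """P(action 0) for a two-option softmax, numerically safe."""
    m = max(pref0, pref1)
    e0 = np.exp(pref0 - m)
    e1 = np.exp(pref1 - m)
    return e0 / (e0 + e1)


def _normalize_phase_params(params_by_phase) -> dict:
    if isinstance(params_by_phase, AgentParams):
        return {"drift": params_by_phase, "stable": params_by_phase}
    out = dict(params_by_phase)
    for phase in ("drift", "stable"):
        if phase not in out:
            raise InvalidConfigError(f"missing agent parameters for phase {phase!r}")
    return out


def simulate_session(
    params_by_phase,
    config: TaskConfig,
    seed=None,
    schedule: RewardSchedule | None = None,
) -> list[TrialRecord]:
    """Simulate one 300-trial session; returns the trial log.

    ``params_by_phase`` is either a single :class:`AgentParams` (used in both
    phases) or a mapping ``{"drift": ..., "stable": ...}``.  The reward
    schedule and the agent's choices share one seeded generator, so the whole
    session is deterministic given ``seed``.
    """
    params = _normalize_phase_params(params_by_phase)
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = config.build_schedule(seed=rng)
    if schedule.n_trials != config.n_trials:
        raise InvalidConfigError(
            f"schedule has {schedule.n_trials} trials; config expects {config.n_trials}"
        )
    struct = config.transition
    p_c = struct.p_common
    common = struct.common_state

    q2 = np.zeros((2, 2))
    qmf = np.zeros(2)
    prev_choice1 = None
    records = []
    for t in range(config.n_trials):
        phase = "drift" if t < config.n_drift else "stable"
        p = params[phase]
        qmb = np.array(
            [
                p_c * q2[common[a]].max() + (1 - p_c) * q2[1 - common[a]].max()
                for a in (0, 1)
            ]
        )
        pref = p.beta1 * (p.w * qmb + (1 - p.w) * qmf)
        if prev_choice1 is not None:
            pref[prev_choice1] += p.persev
        a1 = 0 if rng.random() < _softmax2(pref[0], pref[1]) else 1
        s = common[a1] if rng.random() < p_c else 1 - common[a1]
        trans = "common" if s == common[a1] else "rare"
        a2 = 0 if rng.random() < _softmax2(p.beta2 * q2[s, 0], p.beta2 * q2[s, 1]) else 1
        prob = schedule.probs[t, s, a2]
        r = int(rng.random() < prob)
        # both prediction errors use the pre-update Q2, so at lam=1 the
        # stage-1 update collapses to a pure reward-driven delta rule
        delta1 = q2[s, a2] - qmf[a1]
        delta2 = r - q2[s, a2]
        q2[s, a2] += p.alpha2 * delta2
        qmf[a1] += p.alpha1 * delta1 + p.lam * p.alpha1 * delta2
        records.append(
            TrialRecord(
                trial_index=t + 1,
                phase=phase,
                choice1=STAGE1_ACTIONS[a1],
                transition=trans,
                state2=s + 1,
                choice2=STAGE2_ACTIONS[a2],
                reward=r,
                prob_used=float(prob),
            )
        )
        prev_choice1 = a1
    return records


def simulate_sessions_batch(
    params_by_phase,
    config: TaskConfig,
    n_sessions: int,
    seed=None,
) -> dict:
    """Vectorized twin of :func:`simulate_session` for many i.i.d. sessions.

    All sessions share the same agent parameters but have independent drift
    schedules, transitions, and rewards.  Used for large simulation studies
    (parameter recovery, null-calibration of the ANOVA) where a per-session
    Python loop would be too slow.  Returns arrays of shape
    ``(n_sessions, n_trials)``:

    ``choice1`` (0/1), ``common`` (bool transition label), ``state2``
    (0-based), ``choice2`` (0/1), ``reward`` (0/1), plus the per-trial
    ``phase`` labels of the shared task config.
    """
    params = _normalize_phase_params(params_by_phase)
    rng = np.random.default_rng(seed)
    S, T = n_sessions, config.n_trials
    struct = config.transition
    p_c = struct.p_common
    common = np.asarray(struct.common_state)
    lower, upper = config.drift_bounds
    width = upper - lower

    # current drift reward probabilities, evolved in place
    probs = rng.uniform(lower, upper, size=(S, 2, 2))
    stable = np.broadcast_to(np.asarray(config.stable_probs, dtype=float), (S, 2, 2))

    q2 = np.zeros((S, 2, 2))
    qmf = np.zeros((S, 2))
    prev = np.full(S, -1)
    out_c1 = np.empty((S, T), dtype=np.int8)
    out_common = np.empty((S, T), dtype=bool)
    out_s = np.empty((S, T), dtype=np.int8)
    out_c2 = np.empty((S, T), dtype=np.int8)
    out_r = np.empty((S, T), dtype=np.int8)
    rows = np.arange(S)

    for t in range(T):
        drift = t < config.n_drift
        p = params["drift" if drift else "stable"]
        if drift:
            if t > 0 and config.drift_step_sd > 0:
                probs += rng.normal(0.0, config.drift_step_sd, size=(S, 2, 2))
                y = np.mod(probs - lower, 2 * width)
                probs = np.where(y > width, 2 * width - y, y) + lower
            cur = probs
        else:
            cur = stable
        q2max = q2.max(axis=2)  # (S, 2)
        qmb = p_c * q2max[:, common] + (1 - p_c) * q2max[:, 1 - common]
        pref = p.beta1 * (p.w * qmb + (1 - p.w) * qmf)
        bonus = np.zeros((S, 2))
        seen = prev >= 0
        bonus[rows[seen], prev[seen]] = p.persev
        pref += bonus
        d = pref[:, 0] - pref[:, 1]
        p_a0 = 1.0 / (1.0 + np.exp(-np.clip(d, -700, 700)))
        a1 = (rng.random(S) >= p_a0).astype(np.int8)
        is_common = rng.random(S) < p_c
        s = np.where(is_common, common[a1], 1 - common[a1]).astype(np.int8)
        q2s = q2[rows, s]  # (S, 2)
        d2 = p.beta2 * (q2s[:, 0] - q2s[:, 1])
        p_b0 = 1.0 / (1.0 + np.exp(-np.clip(d2, -700, 700)))
        a2 = (rng.random(S) >= p_b0).astype(np.int8)
        prob = cur[rows, s, a2]
        r = (rng.random(S) < prob).astype(np.int8)
        delta1 = q2[rows, s, a2] - qmf[rows, a1]
        delta2 = r - q2[rows, s, a2]
        q2[rows, s, a2] += p.alpha2 * delta2
        qmf[rows, a1] += p.alpha1 * delta1 + p.lam * p.alpha1 * delta2
        out_c1[:, t] = a1
        out_common[:, t] = is_common
        out_s[:, t] = s
        out_c2[:, t] = a2
        out_r[:, t] = r
        prev = a1

    phase = np.array(
        ["drift" if t < config.n_drift else "stable" for t in range(T)], dtype=object
    )
    return {
        "choice1": out_c1,
        "common": out_common,
        "state2": out_s,
        "choice2": out_c2,
        "reward": out_r,
        "phase": phase,
    }
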