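"""Synthetic cohort generator: participants, genotypes, hormones, sessions.

Emulates the study design: a cohort of naturally cycling women (default 41;
12 Met/Met homozygotes and 29 Val-carriers of the COMT Val158Met
polymorphism), each tested with one 300-trial two-step session in the early
follicular (low estradiol) and one in the late follicular (high estradiol)
cycle phase.  Session behavior comes from the hybrid agent; group-by-phase
effects are injected as additive shifts to the agent parameters via an
*effect map* keyed by (genotype group, cycle phase, task phase).  An all-zero
effect map yields a null cohort.

The default effect map is a calibration choice, not an estimate from data: it
shifts the model-based weight ``w`` of Met/Met agents down in the late-phase
drift block and up in the late-phase stable block, sized so that a default
cohort reproduces the qualitative genotype-by-cycle-phase pattern of the
human tables (drift: model-based decline and model-free rise in Met/Met;
stable: model-free decline in Met/Met; Val-carriers unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .agent import AgentParams, simulate_session
from .errors import InvalidConfigError, InvalidInputError
from .task import TaskConfig, TrialRecord

__all__ = [
    "GENOTYPES",
    "GROUPS",
    "CYCLE_PHASES",
    "DEFAULT_ESTRADIOL_SUMMARY",
    "DEFAULT_EFFECT_MAP",
    "ParticipantProfile",
    "CohortConfig",
    "CohortDataset",
    "draw_genotypes",
    "genotype_group",
    "draw_estradiol",
    "schedule_late_follicular_test",
    "generate_cohort",
]

GENOTYPES = ("Met/Met", "Met/Val", "Val/Val")
GROUPS = ("met_hom", "val_carrier")
CYCLE_PHASES = ("early", "late")

#: salivary estradiol (pg/ml), mean and SEM per genotype group x cycle phase
DEFAULT_ESTRADIOL_SUMMARY = {
    ("met_hom", "early"): (2.98, 0.63),
    ("met_hom", "late"): (3.81, 0.60),
    ("val_carrier", "early"): (3.00, 0.27),
    ("val_carrier", "late"): (4.56, 0.35),
}
#: group sizes the SEMs above were computed from
DEFAULT_ESTRADIOL_N = {"met_hom": 12, "val_carrier": 29}

#: mean cycle length (days), mean and SEM per genotype group
DEFAULT_CYCLE_LENGTH_SUMMARY = {
    "met_hom": (29.2, 1.1),
    "val_carrier": (30.7, 0.7),
}

#: calibrated additive shifts to AgentParams, keyed
#: (genotype group, cycle phase, task phase); unlisted cells are zero.
DEFAULT_EFFECT_MAP = {
    ("met_hom", "late", "drift"): {"w": -0.6},
    ("met_hom", "late", "stable"): {"w": +0.4},
}


def genotype_group(genotype: str) -> str:
    """Met/Met homozygotes vs Val-allele carriers (Met/Val + Val/Val)."""
    if genotype not in GENOTYPES:
        raise InvalidInputError(f"unknown genotype: {genotype!r}")
    return "met_hom" if genotype == "Met/Met" else "val_carrier"


def draw_genotypes(n: int, met_freq: float, rng) -> list[str]:
    """Draw genotypes under Hardy-Weinberg proportions (p^2, 2pq, q^2).

    ``met_freq`` is the Met allele frequency p; Met/Met has probability p^2,
    Met/Val 2p(1-p), Val/Val (1-p)^2.
    """
    if not 0.0 <= met_freq <= 1.0:
        raise InvalidInputError(f"allele frequency must lie in [0, 1]; got {met_freq}")
    p = met_freq
    probs = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    draws = rng.choice(3, size=n, p=probs)
    return [GENOTYPES[i] for i in draws]


def draw_estradiol(
    group: str,
    cycle_phase: str,
    rng,
    summary: dict = None,
    n_source: dict = None,
) -> float:
    """One estradiol value (pg/ml) from a zero-truncated normal.

    The cell SD is reconstructed from the summary SEM as SEM*sqrt(n_source),
    then the normal is truncated at zero (hormone levels are non-negative).
    """
    summary = DEFAULT_ESTRADIOL_SUMMARY if summary is None else summary
    n_source = DEFAULT_ESTRADIOL_N if n_source is None else n_source
    key = (group, cycle_phase)
    if key not in summary:
        raise InvalidConfigError(f"no estradiol summary for cell {key}")
    mean, sem = summary[key]
    if sem < 0:
        raise InvalidConfigError(f"SEM must be non-negative; got {sem}")
    if sem == 0:
        return float(mean)
    sd = sem * np.sqrt(n_source[group])
    a = (0.0 - mean) / sd  # truncate at zero
    return float(sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def schedule_late_follicular_test(mean_cycle_length: float) -> int:
    """Days subtracted from the anticipated cycle end to schedule the
    late-follicular test: 15 for cycles shorter than 28 days, 16 for 28-31
    days, 17 for longer cycles."""
    if mean_cycle_length <= 0:
        raise InvalidInputError(
            f"cycle length must be positive; got {mean_cycle_length}"
        )
    if not 20 <= mean_cycle_length <= 45:
        raise InvalidInputError(
            f"cycle length {mean_cycle_length} outside the plausible 20-45 day range"
        )
    if mean_cycle_length < 28:
        return 15
    if mean_cycle_length <= 31:
        return 16
    return 17


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    genotype: str
    genotype_group: str
    test_order: str  # "early-first" or "late-first"
    mean_cycle_length: float
    estradiol_early: float
    estradiol_late: float

    def __post_init__(self):
        if self.genotype_group != genotype_group(self.genotype):
            raise InvalidConfigError(
                f"genotype_group {self.genotype_group!r} inconsistent with "
                f"genotype {self.genotype!r}"
            )
        if min(self.estradiol_early, self.estradiol_late) < 0:
            raise InvalidConfigError("estradiol values must be non-negative")


@dataclass
class CohortConfig:
    """Cohort composition and effect structure (defaults match the study)."""

    n_met_hom: int = 12
    n_val_carrier: int = 29
    met_allele_freq: float = 49.0 / 82.0
    n_early_first: int = 24
    estradiol_summary: dict = field(default_factory=lambda: dict(DEFAULT_ESTRADIOL_SUMMARY))
    estradiol_n_source: dict = field(default_factory=lambda: dict(DEFAULT_ESTRADIOL_N))
    cycle_length_summary: dict = field(
        default_factory=lambda: dict(DEFAULT_CYCLE_LENGTH_SUMMARY)
    )
    base_params: AgentParams = field(default_factory=AgentParams)
    effect_map: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int | None = None

    def __post_init__(self):
        if self.n_met_hom <= 0 or self.n_val_carrier <= 0:
            raise InvalidConfigError("group counts must be positive")
        if not 0.0 <= self.met_allele_freq <= 1.0:
            raise InvalidConfigError("allele frequency must lie in [0, 1]")
        if not 0 <= self.n_early_first <= self.n_total:
            raise InvalidConfigError(
                f"n_early_first must lie in [0, {self.n_total}]; got {self.n_early_first}"
            )
        for key, (mean, sem) in self.estradiol_summary.items():
            if sem <= 0:
                raise InvalidConfigError(f"estradiol SEM must be positive in cell {key}")

    @property
    def n_total(self) -> int:
        return self.n_met_hom + self.n_val_carrier

    def params_for(self, group: str, cycle_phase: str) -> dict[str, AgentParams]:
        """Agent parameters per task phase for one group x cycle-phase cell."""
        out = {}
        for task_phase in ("drift", "stable"):
            shifts = self.effect_map.get((group, cycle_phase, task_phase), {})
            out[task_phase] = self.base_params.shifted(**shifts)
        return out

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class CohortDataset:
    """Participants plus one trial log per (participant, cycle phase)."""

    participants: list[ParticipantProfile]
    sessions: dict[tuple[str, str], list[TrialRecord]]
    config: CohortConfig
    seed: int | None = None

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def genotype_counts(self) -> tuple[int, int, int]:
        """(Val/Val, Met/Val, Met/Met) counts, minor-homozygote first."""
        gts = [p.genotype for p in self.participants]
        return (gts.count("Val/Val"), gts.count("Met/Val"), gts.count("Met/Met"))


def _carrier_genotype(rng, met_freq: float) -> str:
    # conditional Hardy-Weinberg split of Val-carriers into Met/Val vs Val/Val
    p, q = met_freq, 1.0 - met_freq
    denom = 2 * p * q + q**2
    p_het = 1.0 if denom == 0 else 2 * p * q / denom
    return "Met/Val" if rng.random() < p_het else "Val/Val"


def generate_cohort(config: CohortConfig | None = None, seed=None) -> CohortDataset:
    """Generate a full synthetic cohort.

    Group sizes are fixed by the config (genotypes within the Val-carrier
    group follow conditional Hardy-Weinberg proportions); test order is
    assigned by random permutation with exactly ``n_early_first``
    early-first participants.  Every participant gets an independent child
    seed, so adding a participant does not perturb the others' data.
    """
    config = CohortConfig() if config is None else config
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    cohort_ss, *participant_ss = root.spawn(1 + config.n_total)
    rng = np.random.default_rng(cohort_ss)

    n = config.n_total
    order = np.full(n, "late-first", dtype=object)
    order[rng.permutation(n)[: config.n_early_first]] = "early-first"

    participants = []
    sessions = {}
    for i in range(n):
        pid = f"P{i + 1:03d}"
        prng_ss = participant_ss[i]
        prng = np.random.default_rng(prng_ss)
        if i < config.n_met_hom:
            genotype = "Met/Met"
        else:
            genotype = _carrier_genotype(prng, config.met_allele_freq)
        group = genotype_group(genotype)
        mean_cl, sem_cl = config.cycle_length_summary[group]
        sd_cl = sem_cl * np.sqrt(
            config.n_met_hom if group == "met_hom" else config.n_val_carrier
        )
        cycle_length = float(np.clip(prng.normal(mean_cl, sd_cl), 20.0, 45.0))
        e_early = draw_estradiol(
            group, "early", prng, config.estradiol_summary, config.estradiol_n_source
        )
        e_late = draw_estradiol(
            group, "late", prng, config.estradiol_summary, config.estradiol_n_source
        )
        # enforce the within-woman follicular rise on average by resampling is
        # NOT done: cell means already encode the rise; individual draws vary.
        profile = ParticipantProfile(
            id=pid,
            genotype=genotype,
            genotype_group=group,
            test_order=str(order[i]),
            mean_cycle_length=round(cycle_length, 1),
            estradiol_early=round(e_early, 3),
            estradiol_late=round(e_late, 3),
        )
        participants.append(profile)
        session_ss = prng_ss.spawn(2)
        for cycle_phase, ss in zip(CYCLE_PHASES, session_ss):
            params = config.params_for(group, cycle_phase)
            sessions[(pid, cycle_phase)] = simulate_session(
                params, config.task, seed=np.random.default_rng(ss)
            )
    return CohortDataset(
        participants=participants, sessions=sessions, config=config, seed=seed
    )
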