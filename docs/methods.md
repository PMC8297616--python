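# Methods

## The task

The two-step task is a sequential decision paradigm built to dissociate two
reinforcement-learning strategies. Each of 300 trials has two stages. A
first-stage choice between options A and B leads probabilistically to one of
two second-stage states: each option has a *common* destination reached with
probability 0.7 and a *rare* one reached with probability 0.3 (A commonly
leads to state 1, B to state 2; the mapping is configurable). A second-stage
choice between two options then pays one coin with a state- and
option-specific probability.

Reward probabilities change regime halfway through a session:

* **Drift phase (trials 1–150).** Each of the four (state, option) reward
  probabilities follows an independent Gaussian random walk with step SD
  0.025, reflected at the bounds [0.25, 0.75] and initialized uniformly
  inside them. The walk form, step size, and reflecting (rather than
  clipping) boundary are conventions of the task literature; the original
  experiments used a small fixed set of pre-generated drift trajectories that
  are not public, so seeded walks take their place. Both the step SD and the
  bounds are configuration fields.
* **Stable phase (trials 151–300).** Probabilities are fixed at 0.7 vs 0.3 in
  state 1 and 0.6 vs 0.4 in state 2. The switch is abrupt at trial 151 (it
  was hidden from human subjects, so no interpolation is applied).

Trial indices are 1-based; the phase rule is "index ≤ 150 is drift." The
generative model has no response deadline and no missed trials: the 2-second
response window of the human experiment is a constraint on subjects, not on
task dynamics.

## Stay frequencies and learning scores

For every trial with a predecessor, a *stay* observation records whether the
first-stage choice repeated the previous trial's, classified by the previous
trial's outcome (rewarded/unrewarded) and transition (common/rare). Each
observation belongs to the phase of the *current* trial, so trial 151 —
conditioning on drift trial 150 — counts toward the stable phase; the task is
continuous and the regime switch invisible, so the conditioning trial's phase
would be an arbitrary label. Trial 1 contributes nothing. With the cell
percentages %<sub>rc</sub>, %<sub>rr</sub>, %<sub>uc</sub>, %<sub>ur</sub>:

    MF = %rc + %rr − %uc − %ur        (main effect of previous reward)
    MB = %rc + %ur − %rr − %uc        (reward × transition interaction)

Both are zero-sum linear contrasts in percentage points, bounded by ±200.
Empty cells raise an error naming the cell instead of imputing a value; with
150-trial phases and non-degenerate choice policies the rarest cell
(unrewarded–rare) still expects ≈20 observations, so this is a data-quality
signal, not a routine event. Percentages are carried at full precision and
rounded only when reports are rendered (1 decimal for stay percentages, 2 for
F and effect sizes).

## The hybrid agent

The human analysis computes scores from stay frequencies and fits no
computational model; a generative model is nevertheless needed to produce
synthetic sessions. We use the standard dual-controller ("hybrid") agent.
Second-stage values Q2(s, b) learn by a delta rule with rate α2. First-stage
values mix a model-free estimate Q_MF with a model-based one:

    Q_MB(a) = 0.7 · max_b Q2(s_common(a), b) + 0.3 · max_b Q2(s_rare(a), b)
    pref(a) = β1 · [ w·Q_MB(a) + (1−w)·Q_MF(a) ] + π · 1[a = previous choice]

with softmax choice at both stages (β2 at stage 2). After the outcome r:

    δ1 = Q2(s2, a2) − Q_MF(a1)          (computed before the Q2 update)
    δ2 = r − Q2(s2, a2)
    Q2(s2, a2) += α2 · δ2
    Q_MF(a1)  += α1 · δ1 + λ · α1 · δ2

Both prediction errors use the pre-update Q2. This is the canonical
convention, chosen over the variant that lets the stage-1 target see the
already-updated Q2 because it makes the λ = 1, w = 0 agent collapse exactly
to a reward-driven delta rule — the defining property of a pure model-free
controller, and the property the parameter-recovery tests rely on. Q-values
carry over the phase boundary; only the parameters may switch there.

Defaults (α1 = α2 = 0.5, β1 = 4, β2 = 2.5, λ = 0.6, w = 0.6, π = 1) were
chosen once so that a default agent produces human-scale behavior: overall
stay rates near 70–80%, model-free scores ≈ 15–25 and model-based scores
≈ 10–15 on the ±200 scale. `simulate_sessions_batch` is a vectorized twin of
the per-session simulator (same update equations, different draw order) used
for large simulation studies; a test checks the two agree statistically.

## The synthetic cohort

`generate_cohort` emulates the study sample: 41 women — 12 Met/Met
homozygotes and 29 Val-carriers of the COMT Val158Met polymorphism — each
contributing one session in the early follicular (low estradiol) and one in
the late follicular (high estradiol) cycle phase, with 24 participants tested
early-first. Genotypes inside the Val-carrier group split into Met/Val vs
Val/Val by conditional Hardy–Weinberg proportions at Met allele frequency
49/82. Estradiol values are drawn per participant from zero-truncated
normals whose cell means/SEMs are the published group summaries (e.g.
Met/Met early 2.98 ± 0.63 pg/ml, Val-carrier late 4.56 ± 0.35 pg/ml), with
the SD reconstructed as SEM·√n. The five-sample morning averaging of the
assay is collapsed into the single drawn value; no within-cycle hormone
kinetics are modeled. The late-follicular scheduling rule (subtract 15/16/17
days from the anticipated cycle end for cycles <28 / 28–31 / >31 days) is
implemented as a standalone utility.

Group-by-phase effects enter as additive shifts to agent parameters via an
*effect map* keyed by (genotype group, cycle phase, task phase). The default
map is a calibration, not an estimate — the study reports no effects in
agent-parameter space, so there is no ground truth to recover:

    Met/Met, late, drift  : w − 0.6   (model-based collapse under volatility)
    Met/Met, late, stable : w + 0.4   (model-free withdrawal under stability)

All other cells are zero, so Val-carriers are unaffected by cycle phase.
These two shifts were sized so that a default 41-participant cohort
reproduces the qualitative human pattern — Met/Met: drift-phase model-based
decline, drift model-free rise, stable model-free decline; Val-carriers: no
systematic change — in well over 80% of seeded cohorts, while leaving
group-average scores in the human range. An all-zero effect map yields a
null cohort used for type-I-error calibration. Because shifted parameters
are clipped to their legal ranges, the late-drift Met/Met agent is purely
model-free (w = 0) and the late-stable one purely model-based (w = 1); the
injection is deliberately simple and should be read as a sign-pattern
generator, not a mechanistic hormone model.

What passing tests on this generator do **not** show: anything about real
menstrual-cycle physiology, real genotype effects, or the fit of the hybrid
model to human choices. They show that the analysis pipeline measures what
it claims to measure on data whose ground truth is known.

Seeding: a single root seed spawns one child seed per participant (and one
per session below that) via `numpy` SeedSequence, so cohorts are bit
reproducible and adding a participant does not perturb the others.

## Statistics

**Mixed ANOVA.** Designs with up to three two-level within-subject factors
crossed with one between-subjects factor. Every within effect is reduced to
one contrast score per subject (product of ±1 codes over cells, averaged),
then tested in the one-way cell-means model against its own
subject-by-effect residual — the classical univariate decomposition. All
within factors having two levels makes sphericity hold trivially and gives
every effect 1 numerator df and N − G denominator df (1 and 39 for the
default cohort). With unequal groups (12 vs 29), within effects test the
*unweighted* (Type III) grand mean of group means, and between-involving
effects the cell-means GLM contrast, because no software or SS type is named
in the source report and Type III is what the major commercial packages
print for this design. Unit tests verify every F against statsmodels'
Type III OLS on the contrast scores (unbalanced case) and against pingouin's
mixed ANOVA (balanced case) to ~1e-8, and re-verify the identity
η²ₚ = SS_eff/(SS_eff+SS_err) = F·df1/(F·df1+df2) on every row. Constant
input (zero error SS and zero effect SS) is reported as F = 0, p = 1.

**t-tests.** Paired t with effect size mean(diff)/SD(diff); pooled-variance
independent t with df = n1 + n2 − 2 (the printed df "39" implies pooling, so
Welch is not used). `independent_t_from_summary` rebuilds the pooled t from
per-group mean/SEM/n, recovering SDs as SEM·√n. Standardized between-group
differences use d_s = t·√(1/n1 + 1/n2); the small-sample Hedges factor
1 − 3/(4·df − 1) is available but **off by default**, because the source
tables' printed "Hedges' g" values match the uncorrected form. Zero-variance
inputs return a flagged degenerate result (t = 0, p = 1) rather than NaN.
Tests are two-tailed except the estradiol cycle-phase rise, which the
pipeline tests one-tailed as in the original design.

**Hardy–Weinberg exact test.** Full enumeration of the conditional
distribution of the heterozygote count given the allele counts (log-gamma
arithmetic; the distribution sums to 1 by construction and by test). Two
two-sided conventions are exposed: the usual "as-or-less-probable" rule
(default) and a doubled-minimal-tail rule. For genotype counts (4, 25, 12)
these give p = 0.118 and p = 0.185 respectively; third-party genotyping QC
tools differ on exactly this convention, which is why both are provided.

## Pipeline

`run_full_analysis` = simulate (or load) → tabulate → score → test → report.
Intermediates are TSVs with full-precision floats (round-trip float parsing
on read); the report directory contains `scores.tsv` (one row per
participant × cycle phase × task phase), the two 15-row stay-frequency ANOVA
tables, four cycle-phase × test-order ANOVAs (one per task phase and score),
a t-test table in the genotype × cycle-phase layout, score-delta vs
coin-delta Pearson correlations, estradiol tests, and a plain-text summary.
Reports are byte-stable given the same inputs, and a test verifies that the
staged path through on-disk intermediates equals the in-memory path.

## Problem sizes used by the test suite

Simulation-based checks use: 10⁵ draws for transition/reward rate
calibration; 100 seeded schedules for drift bounds; 300 sessions per w level
for parameter recovery; 2000 null cohorts of 20 subjects for the ANOVA
type-I calibration (each truly-null effect must reject in 5% ± 1.5% of
cohorts; the two genuinely non-null behavioral effects must exceed 90%
power); and 50 default cohorts for the genotype-by-cycle sign pattern (≥80%
reproduction required). These sizes give Monte-Carlo standard errors
comfortably below the asserted tolerances.

## Known limitations

* The effect map is a sign-pattern calibration; magnitudes of the injected
  effects are not matched to the human deltas beyond being the same order.
* Agents are homogeneous within a group×phase cell (no between-subject
  parameter variability), so between-subject variance is purely binomial
  sampling noise — smaller than in humans.
* No missed trials, reaction times, or dropout are modeled; readers of
  external logs should document their own exclusion rules before scoring.
* The exact drift process of the original stimuli (autocorrelation,
  boundary handling) is unknown; only its stated envelope is honored.
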