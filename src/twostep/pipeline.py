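"""End-to-end analysis recipe: simulate → tabulate → score → test → report.

`run_full_analysis` reproduces the study's full statistical pipeline on a
cohort dataset (simulated or loaded from disk):

1. stay-frequency tabulation per session and task phase;
2. model-free / model-based scores and coin totals;
3. drift- and stable-phase mixed ANOVAs on stay frequencies with within
   factors previous reward, previous transition, cycle phase and between
   factor genotype group (15 effect rows each);
4. score comparisons in the genotype-by-cycle-phase layout (paired t within
   genotype, pooled independent t between genotypes, and between-genotype
   tests on late-minus-early deltas);
5. Pearson correlations of the score deltas with the coin-total delta;
6. cycle-phase x test-order ANOVAs per task phase and score component;
7. a one-tailed paired t-test on the estradiol rise and an exact
   Hardy-Weinberg test on the cohort's genotype counts.

All numbers are kept at full precision in the report object; rounding happens
only when rendering tables to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tsio
from .cohort import CohortConfig, CohortDataset, generate_cohort
from .errors import InvalidInputError
from .metrics import (
    CELLS,
    learning_scores,
    tabulate_stays,
    total_coins,
)
from .stats import (
    GenotypeCounts,
    hwe_exact_test,
    independent_t,
    mixed_anova,
    paired_t,
    pearson_r,
)

__all__ = ["AnalysisReport", "score_cohort", "analyze_cohort", "run_full_analysis", "write_report"]

TASK_PHASES = ("drift", "stable")
_CELL_SHORT = {"rewarded_common": "rc", "rewarded_rare": "rr",
               "unrewarded_common": "uc", "unrewarded_rare": "ur"}


@dataclass
class AnalysisReport:
    scores: pd.DataFrame
    stay_anova: dict
    test_order_anova: dict
    score_ttests: pd.DataFrame
    correlations: pd.DataFrame
    estradiol_tests: pd.DataFrame
    hwe: dict
    provenance: dict = field(default_factory=dict)


def score_cohort(dataset: CohortDataset) -> pd.DataFrame:
    """Per session-phase stay table, learning scores, and coin totals.

    One row per participant x cycle phase x task phase (164 for the default
    cohort).  Stay percentages are carried at full precision.
    """
    rows = []
    by_id = {p.id: p for p in dataset.participants}
    for (pid, cycle_phase), records in dataset.sessions.items():
        profile = by_id[pid]
        for task_phase in TASK_PHASES:
            table = tabulate_stays(records, phase=task_phase)
            scores = learning_scores(table)
            pct = table.stay_pct
            row = {
                "participant": pid,
                "genotype": profile.genotype,
                "group": profile.genotype_group,
                "test_order": profile.test_order,
                "cycle_phase": cycle_phase,
                "task_phase": task_phase,
            }
            for cell in CELLS:
                row[f"stay_{_CELL_SHORT[cell]}"] = pct[cell]
                row[f"n_{_CELL_SHORT[cell]}"] = table.n_obs[cell]
            row["mf_score"] = scores.model_free
            row["mb_score"] = scores.model_based
            row["coins"] = total_coins(records, phase=task_phase)
            rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["participant", "cycle_phase", "task_phase"], kind="stable"
    ).reset_index(drop=True)


def _stay_long(scores: pd.DataFrame, task_phase: str) -> pd.DataFrame:
    sub = scores[scores["task_phase"] == task_phase]
    rows = []
    for r in sub.itertuples(index=False):
        for cell in CELLS:
            reward, transition = cell.split("_")
            rows.append(
                {
                    "participant": r.participant,
                    "group": r.group,
                    "test_order": r.test_order,
                    "cycle_phase": r.cycle_phase,
                    "previous_reward": reward,
                    "previous_transition": transition,
                    "stay_pct": getattr(r, f"stay_{_CELL_SHORT[cell]}"),
                }
            )
    return pd.DataFrame(rows)


def _paired_frame(scores: pd.DataFrame, task_phase: str, value: str) -> pd.DataFrame:
    """participant x cycle-phase wide frame for one score column."""
    sub = scores[scores["task_phase"] == task_phase]
    wide = sub.pivot(index="participant", columns="cycle_phase", values=value)
    meta = sub.drop_duplicates("participant").set_index("participant")["group"]
    wide["group"] = meta
    return wide


def analyze_cohort(dataset: CohortDataset) -> AnalysisReport:
    scores = score_cohort(dataset)
    if scores[[c for c in scores.columns if c.startswith("stay_")]].isna().any().any():
        bad = scores[scores.isna().any(axis=1)].iloc[0]
        raise InvalidInputError(
            f"undefined stay cell for participant {bad['participant']} "
            f"({bad['cycle_phase']}/{bad['task_phase']})"
        )

    stay_anova = {}
    for task_phase in TASK_PHASES:
        stay_anova[task_phase] = mixed_anova(
            _stay_long(scores, task_phase),
            dv="stay_pct",
            subject="participant",
            within=["previous_reward", "previous_transition", "cycle_phase"],
            between="group",
        )

    # cycle phase x test order, per task phase and learning component
    test_order_anova = {}
    for task_phase in TASK_PHASES:
        for score_col, label in (("mf_score", "model_free"), ("mb_score", "model_based")):
            long = scores[scores["task_phase"] == task_phase][
                ["participant", "test_order", "cycle_phase", score_col]
            ].rename(columns={score_col: "score"})
            test_order_anova[(task_phase, label)] = mixed_anova(
                long,
                dv="score",
                subject="participant",
                within=["cycle_phase"],
                between="test_order",
            )

    # genotype-by-cycle-phase score comparisons
    trows = []
    deltas = {}
    for task_phase in TASK_PHASES:
        for score_col, label in (("mf_score", "model_free"), ("mb_score", "model_based")):
            wide = _paired_frame(scores, task_phase, score_col)
            deltas[(task_phase, label)] = wide["late"] - wide["early"]
            for group, sub in wide.groupby("group"):
                res = paired_t(sub["late"], sub["early"])
                trows.append(
                    {
                        "task_phase": task_phase,
                        "score": label,
                        "comparison": f"late_vs_early_within_{group}",
                        "kind": "paired",
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "effect_size": res.effect_size,
                        "effect_kind": res.effect_kind,
                    }
                )
            met = wide[wide["group"] == "met_hom"]
            val = wide[wide["group"] == "val_carrier"]
            for cycle_phase in ("early", "late"):
                res = independent_t(met[cycle_phase], val[cycle_phase])
                trows.append(
                    {
                        "task_phase": task_phase,
                        "score": label,
                        "comparison": f"met_vs_val_{cycle_phase}",
                        "kind": "independent",
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "effect_size": res.effect_size,
                        "effect_kind": res.effect_kind,
                    }
                )
            d = wide["late"] - wide["early"]
            res = independent_t(
                d[wide["group"] == "met_hom"], d[wide["group"] == "val_carrier"]
            )
            trows.append(
                {
                    "task_phase": task_phase,
                    "score": label,
                    "comparison": "delta_met_vs_val",
                    "kind": "independent",
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "effect_size": res.effect_size,
                    "effect_kind": res.effect_kind,
                }
            )
    score_ttests = pd.DataFrame(trows)

    # score deltas vs coin-total deltas
    crows = []
    for task_phase in TASK_PHASES:
        coins = _paired_frame(scores, task_phase, "coins")
        dcoins = coins["late"] - coins["early"]
        for label in ("model_free", "model_based"):
            d = deltas[(task_phase, label)]
            res = pearson_r(d.loc[dcoins.index], dcoins)
            crows.append(
                {
                    "task_phase": task_phase,
                    "x": f"delta_{label}",
                    "y": "delta_coins",
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    correlations = pd.DataFrame(crows)

    # estradiol rise, one-tailed (late > early), overall and per group
    parts = pd.DataFrame(
        {
            "group": [p.genotype_group for p in dataset.participants],
            "early": [p.estradiol_early for p in dataset.participants],
            "late": [p.estradiol_late for p in dataset.participants],
        }
    )
    erows = []
    for name, sub in [("all", parts)] + list(parts.groupby("group")):
        res = paired_t(sub["late"], sub["early"], tail="greater")
        erows.append(
            {
                "group": name,
                "mean_early": sub["early"].mean(),
                "mean_late": sub["late"].mean(),
                "t": res.t,
                "df": res.df,
                "p_one_tailed": res.p,
                "d": res.effect_size,
            }
        )
    estradiol_tests = pd.DataFrame(erows)

    counts = dataset.genotype_counts()
    hwe = {
        "counts_valval_metval_metmet": counts,
        "p_as_or_less_probable": hwe_exact_test(GenotypeCounts(*counts)),
        "p_doubled_tail": hwe_exact_test(GenotypeCounts(*counts), method="doubled_tail"),
    }

    provenance = {
        "seed": dataset.seed,
        "config_hash": tsio.config_hash(dataset.config),
        "n_participants": dataset.n_participants,
        "n_sessions": dataset.n_sessions,
    }
    return AnalysisReport(
        scores=scores,
        stay_anova=stay_anova,
        test_order_anova=test_order_anova,
        score_ttests=score_ttests,
        correlations=correlations,
        estradiol_tests=estradiol_tests,
        hwe=hwe,
        provenance=provenance,
    )


def run_full_analysis(
    config: CohortConfig | None = None,
    cohort: CohortDataset | None = None,
    seed=None,
) -> AnalysisReport:
    """Simulate (unless a cohort is supplied) and run the whole pipeline."""
    if cohort is None:
        cohort = generate_cohort(config, seed=seed)
    return analyze_cohort(cohort)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _round_anova(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["F"] = out["F"].round(2)
    out["df"] = out.apply(lambda r: f"{int(r.df1)}, {int(r.df2)}", axis=1)
    out["p"] = out["p"].round(3)
    out["partial_eta_sq"] = out["partial_eta_sq"].round(2)
    return out[["effect", "F", "df", "p", "partial_eta_sq"]]


def write_report(report: AnalysisReport, outdir) -> None:
    """Write the report as TSV tables plus a plain-text summary.

    Output is deterministic given the input report (no timestamps); rounding
    mirrors the conventions of the study's tables (F and partial eta squared
    to 2 decimals, stay percentages to 1 decimal).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scores = report.scores.copy()
    for col in scores.columns:
        if col.startswith("stay_"):
            scores[col] = scores[col].round(1)
        elif col in ("mf_score", "mb_score"):
            scores[col] = scores[col].round(2)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)

    for task_phase, table in report.stay_anova.items():
        _round_anova(table).to_csv(
            outdir / f"anova_stay_{task_phase}.tsv", sep="\t", index=False
        )
    to_rows = []
    for (task_phase, label), table in report.test_order_anova.items():
        rounded = _round_anova(table)
        rounded.insert(0, "score", label)
        rounded.insert(0, "task_phase", task_phase)
        to_rows.append(rounded)
    pd.concat(to_rows, ignore_index=True).to_csv(
        outdir / "anova_test_order.tsv", sep="\t", index=False
    )

    tt = report.score_ttests.copy()
    for col, nd in (("t", 2), ("p", 3), ("effect_size", 2)):
        tt[col] = tt[col].round(nd)
    tt.to_csv(outdir / "ttest_report.tsv", sep="\t", index=False)

    corr = report.correlations.copy()
    corr["r"] = corr["r"].round(3)
    corr["p"] = corr["p"].round(3)
    corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)

    est = report.estradiol_tests.copy()
    for col in ("mean_early", "mean_late", "t", "p_one_tailed", "d"):
        est[col] = est[col].round(3)
    est.to_csv(outdir / "estradiol.tsv", sep="\t", index=False)

    lines = ["two-step task analysis report", "=" * 30, ""]
    lines.append(f"seed: {report.provenance.get('seed')}")
    lines.append(f"config hash: {report.provenance.get('config_hash')}")
    lines.append(f"participants: {report.provenance.get('n_participants')}")
    lines.append("")
    counts = report.hwe["counts_valval_metval_metmet"]
    lines.append(
        f"genotype counts (Val/Val, Met/Val, Met/Met): {counts}; "
        f"HWE exact p = {report.hwe['p_as_or_less_probable']:.3f} "
        f"(doubled-tail {report.hwe['p_doubled_tail']:.3f})"
    )
    lines.append("")
    for task_phase, table in report.stay_anova.items():
        lines.append(f"stay-frequency ANOVA, {task_phase} phase:")
        lines.append(_round_anova(table).to_string(index=False))
        lines.append("")
    lines.append("score t-tests:")
    lines.append(tt.to_string(index=False))
    lines.append("")
    lines.append("score-delta vs coin-delta correlations:")
    lines.append(corr.to_string(index=False))
    lines.append("")
    lines.append("estradiol (one-tailed, late > early):")
    lines.append(est.to_string(index=False))
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
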