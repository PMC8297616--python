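"""Factorial statistics for the stay-frequency analyses.

Implements the inferential toolkit used on the two-step task scores:

* a mixed repeated-measures ANOVA for designs with up to three two-level
  within-subject factors crossed with one between-subjects factor (unequal
  group sizes allowed), reporting F, degrees of freedom, p, and partial eta
  squared for every main effect and interaction;
* paired and pooled-variance independent t-tests, including reconstruction
  from printed summary statistics (mean, SEM, n per group);
* standardized mean differences derived from t (Cohen's d for paired designs,
  d_s / Hedges-corrected g for between-group designs);
* Pearson correlation with the t-transform p-value;
* an exact conditional Hardy-Weinberg equilibrium test.

The ANOVA uses the classical univariate decomposition: every two-level
within-subject effect is reduced to one contrast score per subject, which is
tested against its own subject-by-effect error term.  Because all within
factors have two levels, sphericity holds trivially and every within effect
has 1 numerator df.  With unequal between groups, within effects are tested
via the unweighted (Type III) grand mean of the group means, and
between-involving effects via the cell-means general linear model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "mixed_anova",
    "partial_eta_sq",
    "TTestResult",
    "paired_t",
    "independent_t",
    "independent_t_from_summary",
    "standardized_diff_from_t",
    "CorrelationResult",
    "pearson_r",
    "GenotypeCounts",
    "hwe_exact_test",
    "hwe_het_distribution",
]

_EPS = 1e-12


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise InvalidInputError(f"F must be non-negative; got {F}")
    if df1 <= 0 or df2 <= 0:
        raise InvalidInputError(f"degrees of freedom must be positive; got {df1}, {df2}")
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _oneway_cell_means(y: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """Type III tests in the one-way cell-means model y_i = mu_g + e_i.

    Returns (ss_intercept, ss_group, ss_resid, df_resid).  The intercept is
    the *unweighted* mean of group means (Type III convention for unequal
    group sizes); the group effect is the usual equality-of-means test.
    """
    ns = np.bincount(group_idx, minlength=n_groups).astype(float)
    means = np.bincount(group_idx, weights=y, minlength=n_groups) / ns
    resid = y - means[group_idx]
    ss_resid = float(resid @ resid)
    df_resid = len(y) - n_groups
    mu = means.mean()
    ss_intercept = mu**2 / ((1.0 / ns).sum() / n_groups**2)
    grand = (ns * means).sum() / ns.sum()
    ss_group = float((ns * (means - grand) ** 2).sum())
    return ss_intercept, ss_group, ss_resid, df_resid


def _f_and_p(ss_eff: float, df1: int, ss_err: float, df2: int, scale: float):
    """F ratio with graceful handling of an exactly-zero error term."""
    if df2 <= 0:
        raise InvalidInputError("non-positive error degrees of freedom")
    tiny = _EPS * max(scale, 1.0)
    if ss_err <= tiny:
        if ss_eff <= tiny:
            return 0.0, 1.0
        return np.inf, 0.0
    F = (ss_eff / df1) / (ss_err / df2)
    return F, float(sps.f.sf(F, df1, df2))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA for 2-level within factors.

    ``data`` is long format: one row per subject x within-cell.  Every
    subject must contribute exactly one observation per within cell, and (if
    ``between`` is given) belong to exactly one group with at least two
    subjects.  Returns a table with one row per effect in standard order
    (main effects, then two-way, three-way, ... interactions), with columns
    ``effect, F, df1, df2, p, partial_eta_sq, ss_effect, ss_error``.
    """
    within = list(within)
    if not 1 <= len(within) <= 3:
        raise InvalidInputError("between one and three within factors are supported")
    for col in [dv, subject, *within] + ([between] if between else []):
        if col not in data.columns:
            raise InvalidInputError(f"column {col!r} not found in data")

    levels = {}
    for f in within:
        lv = list(pd.unique(data[f]))
        if len(lv) != 2:
            raise InvalidInputError(
                f"within factor {f!r} must have exactly 2 levels; got {lv}"
            )
        levels[f] = lv

    counts = data.groupby([subject, *within], sort=False, observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise InvalidInputError(
            f"subject {bad[0]!r} has {counts[counts != 1].iloc[0]} observations "
            f"in within cell {bad[1:]}; exactly one is required"
        )
    n_cells = 2 ** len(within)
    per_subject = data.groupby(subject, sort=False).size()
    incomplete = per_subject[per_subject != n_cells]
    if len(incomplete):
        raise InvalidInputError(
            f"subject {incomplete.index[0]!r} is missing within cells "
            f"({incomplete.iloc[0]} of {n_cells} present)"
        )

    # wide layout: subjects x within cells, cells in a fixed lexicographic order
    cell_order = list(itertools.product(*(levels[f] for f in within)))
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, observed=True, aggfunc="first"
    )
    cols = cell_order if len(within) > 1 else [c[0] for c in cell_order]
    Y = wide[cols].to_numpy(dtype=float)
    subjects = wide.index
    n_subj = len(subjects)

    if between is not None:
        gmap = data.groupby(subject, sort=False)[between].agg(pd.unique)
        if gmap.map(len).max() > 1:
            bad = gmap[gmap.map(len) > 1].index[0]
            raise InvalidInputError(f"subject {bad!r} appears in more than one group")
        glabels = gmap.loc[subjects].map(lambda a: a[0])
        group_levels = list(pd.unique(data[between]))
        group_idx = np.array([group_levels.index(g) for g in glabels])
        n_groups = len(group_levels)
        sizes = np.bincount(group_idx, minlength=n_groups)
        if (sizes < 2).any():
            small = group_levels[int(np.argmin(sizes))]
            raise InvalidInputError(
                f"group {small!r} has fewer than 2 subjects ({sizes.min()})"
            )
    else:
        group_idx = np.zeros(n_subj, dtype=int)
        n_groups = 1
        if n_subj < 2:
            raise InvalidInputError("at least 2 subjects are required")

    # +1/-1 codes per factor, aligned with the cell order
    codes = {}
    for f in within:
        codes[f] = np.array(
            [1.0 if cell[within.index(f)] == levels[f][0] else -1.0 for cell in cell_order]
        )

    scale = float(np.var(Y)) * n_subj + 1.0
    factors = within + ([between] if between else [])
    rows = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            w_part = [f for f in combo if f in within]
            has_between = between is not None and between in combo
            if w_part:
                c = np.ones(n_cells)
                for f in w_part:
                    c = c * codes[f]
                y = Y @ (c / n_cells)  # per-subject contrast score
            else:
                y = Y.mean(axis=1)  # subject means: between-subjects stratum
            ss_int, ss_grp, ss_res, df_res = _oneway_cell_means(y, group_idx, n_groups)
            if has_between and not w_part:
                ss_eff, df1 = ss_grp, n_groups - 1
            elif has_between:
                ss_eff, df1 = ss_grp, n_groups - 1
            else:
                ss_eff, df1 = ss_int, 1
            F, p = _f_and_p(ss_eff, df1, ss_res, df_res, scale)
            eta = partial_eta_sq(F, df1, df_res) if np.isfinite(F) else 1.0
            rows.append(
                {
                    "effect": " × ".join(combo),
                    "F": F,
                    "df1": df1,
                    "df2": df_res,
                    "p": p,
                    "partial_eta_sq": eta,
                    "ss_effect": ss_eff,
                    "ss_error": ss_res,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t-tests and standardized effect sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    effect_size: float
    effect_kind: str
    tail: str = "two-sided"
    degenerate: bool = False


def _tail_p(t: float, df: float, tail: str) -> float:
    if tail == "two-sided":
        return float(2 * sps.t.sf(abs(t), df))
    if tail == "greater":
        return float(sps.t.sf(t, df))
    if tail == "less":
        return float(sps.t.cdf(t, df))
    raise InvalidInputError(f"unknown tail: {tail!r}")


def paired_t(x, y, tail: str = "two-sided") -> TTestResult:
    """Paired t-test on x - y; effect size d = mean(diff)/SD(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError(
            f"paired samples must be 1-d and equal length; got {x.shape} vs {y.shape}"
        )
    n = len(x)
    if n < 2:
        raise InvalidInputError("paired t-test needs at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    df = n - 1
    if sd <= _EPS * max(1.0, np.abs(diff).max(initial=0.0)):
        m = diff.mean()
        if abs(m) <= _EPS:
            return TTestResult(0.0, df, 1.0, 0.0, "paired-d", tail, degenerate=True)
        t = np.inf if m > 0 else -np.inf
        return TTestResult(
            t, df, _tail_p(t, df, tail), np.sign(m) * np.inf, "paired-d", tail, True
        )
    t = diff.mean() / (sd / np.sqrt(n))
    return TTestResult(
        t=float(t),
        df=df,
        p=_tail_p(t, df, tail),
        effect_size=float(diff.mean() / sd),
        effect_kind="paired-d",
        tail=tail,
    )


def independent_t(x, y, tail: str = "two-sided", corrected: bool = False) -> TTestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both groups need at least 2 observations")
    return independent_t_from_summary(
        x.mean(),
        x.std(ddof=1) / np.sqrt(n1),
        n1,
        y.mean(),
        y.std(ddof=1) / np.sqrt(n2),
        n2,
        tail=tail,
        corrected=corrected,
    )


def independent_t_from_summary(
    m1: float,
    sem1: float,
    n1: int,
    m2: float,
    sem2: float,
    n2: int,
    tail: str = "two-sided",
    corrected: bool = False,
) -> TTestResult:
    """Pooled t reconstructed from per-group mean, SEM, and n.

    Group SDs are recovered as SEM*sqrt(n); this reproduces printed t values
    from summary tables exactly up to their input rounding.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both groups need n >= 2")
    if sem1 < 0 or sem2 < 0:
        raise InvalidInputError("SEMs must be non-negative")
    sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if denom <= _EPS * max(1.0, abs(m1), abs(m2)):
        if abs(m1 - m2) <= _EPS:
            return TTestResult(0.0, df, 1.0, 0.0, "between-d", tail, degenerate=True)
        t = np.inf if m1 > m2 else -np.inf
        return TTestResult(t, df, _tail_p(t, df, tail), t, "between-d", tail, True)
    t = float((m1 - m2) / denom)
    es = standardized_diff_from_t(t, n1, n2, corrected=corrected)
    kind = "between-g-corrected" if corrected else "between-d"
    return TTestResult(t=t, df=df, p=_tail_p(t, df, tail), effect_size=es, effect_kind=kind, tail=tail)


def standardized_diff_from_t(t: float, n1: int, n2: int, corrected: bool = False) -> float:
    """Standardized between-group mean difference from a pooled t statistic.

    The uncorrected form is d_s = t * sqrt(1/n1 + 1/n2).  ``corrected=True``
    applies the small-sample (Hedges) factor 1 - 3/(4*(n1+n2-2) - 1).  Printed
    "Hedges' g" values in the study's tables match the uncorrected form, which
    is therefore the reporting default.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both groups need n >= 2")
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    if corrected:
        d *= 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float(d)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def pearson_r(x, y, tail: str = "two-sided") -> CorrelationResult:
    """Pearson product-moment correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("samples must be 1-d and equal length")
    n = len(x)
    if n < 3:
        raise InvalidInputError("correlation needs at least 3 points")
    if x.std() <= _EPS * max(1.0, np.abs(x).max()) or y.std() <= _EPS * max(
        1.0, np.abs(y).max()
    ):
        return CorrelationResult(np.nan, np.nan, n, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = _tail_p(t, df, tail)
    return CorrelationResult(r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom1: int
    n_het: int
    n_hom2: int

    def __post_init__(self):
        if min(self.n_hom1, self.n_het, self.n_hom2) < 0:
            raise InvalidInputError("genotype counts must be non-negative")
        if self.n_hom1 + self.n_het + self.n_hom2 < 1:
            raise InvalidInputError("at least one individual is required")


def _coerce_counts(counts) -> GenotypeCounts:
    if isinstance(counts, GenotypeCounts):
        return counts
    return GenotypeCounts(*counts)


def hwe_het_distribution(counts) -> dict[int, float]:
    """Exact conditional distribution of the heterozygote count.

    Conditions on the observed allele counts; the support is every
    heterozygote count with the same parity as the minor-allele count.  The
    probabilities sum to 1.
    """
    c = _coerce_counts(counts)
    n = c.n_hom1 + c.n_het + c.n_hom2
    n_minor = min(2 * c.n_hom1 + c.n_het, 2 * c.n_hom2 + c.n_het)
    logp = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        n_minor_hom = (n_minor - h) // 2
        n_major_hom = n - h - n_minor_hom
        if n_major_hom < 0:
            continue
        logp[h] = (
            lgamma(n + 1)
            - lgamma(n_minor_hom + 1)
            - lgamma(h + 1)
            - lgamma(n_major_hom + 1)
            + h * log(2)
            + lgamma(n_minor + 1)
            + lgamma(2 * n - n_minor + 1)
            - lgamma(2 * n + 1)
        )
    mx = max(logp.values())
    z = sum(np.exp(v - mx) for v in logp.values())
    return {h: float(np.exp(v - mx) / z) for h, v in logp.items()}


def hwe_exact_test(counts, method: str = "as_or_less_probable") -> float:
    """Exact conditional Hardy-Weinberg equilibrium test (two-sided).

    ``method`` selects the two-sided convention:

    * ``"as_or_less_probable"`` — sum the probabilities of all heterozygote
      counts whose conditional probability does not exceed the observed
      table's (the common exact-test definition).
    * ``"doubled_tail"`` — twice the smaller tail probability, capped at 1
      (the convention used by some genotyping QC tools).
    """
    c = _coerce_counts(counts)
    dist = hwe_het_distribution(c)
    p_obs = dist[c.n_het]
    if method == "as_or_less_probable":
        return min(1.0, sum(p for p in dist.values() if p <= p_obs * (1 + 1e-9)))
    if method == "doubled_tail":
        upper = sum(p for h, p in dist.items() if h >= c.n_het)
        lower = sum(p for h, p in dist.items() if h <= c.n_het)
        return min(1.0, 2.0 * min(upper, lower))
    raise InvalidConfigError(f"unknown HWE method: {method!r}")
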