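"""Derivable identities of the reported statistics.

Effect sizes in factorial reports are fully determined by the test
statistics and sample sizes, so they can be recomputed and checked: partial
eta^2 from (F, df), standardized group differences from t, pooled t from
group summary statistics, and the Hardy-Weinberg exact probability from the
genotype counts (4 Val/Val, 25 Met/Val, 12 Met/Met).
"""

from twostep import (
    GenotypeCounts,
    hwe_exact_test,
    independent_t_from_summary,
    partial_eta_sq,
    standardized_diff_from_t,
)

print("partial eta^2 from F(1, 39):")
for F in (39.63, 45.22, 18.60, 9.80, 8.30, 6.56, 4.48):
    print(f"  F = {F:6.2f}  ->  eta_p^2 = {partial_eta_sq(F, 1, 39):.2f}")

print("\nstandardized group difference from t (groups n = 12 and 29):")
for t in (2.74, 2.88, 2.35):
    d = standardized_diff_from_t(t, 12, 29)
    g = standardized_diff_from_t(t, 12, 29, corrected=True)
    print(f"  t = {t:.2f}  ->  d_s = {d:.2f}  (Hedges-corrected {g:.2f})")

print("\npooled t from group summaries (mean ± SEM, n):")
res = independent_t_from_summary(9.2, 4.5, 12, -3.1, 2.8, 29)
print(f"  9.2±4.5 (12) vs -3.1±2.8 (29)  ->  t({res.df}) = {res.t:.2f}, p = {res.p:.3f}")
res = independent_t_from_summary(7.27, 3.35, 12, -3.8, 2.19, 29)
print(f"  7.27±3.35 (12) vs -3.8±2.19 (29) ->  t({res.df}) = {res.t:.2f}, p = {res.p:.3f}")

counts = GenotypeCounts(4, 25, 12)
print("\nHardy-Weinberg exact test on genotype counts (4, 25, 12):")
print(f"  as-or-less-probable two-sided p = {hwe_exact_test(counts):.3f}")
print(f"  doubled-tail two-sided p        = {hwe_exact_test(counts, method='doubled_tail'):.3f}")
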