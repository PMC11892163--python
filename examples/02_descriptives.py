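"""Design-based prevalence estimates with the conservative CI-overlap rule.

Weighted prevalences carry Taylor-linearised (stratum/PSU) variances and
logit-scale 95% intervals. Two groups are flagged as different only when
their intervals are disjoint — deliberately conservative.
"""

import survmediate as sm

params = sm.default_params("female")
cohort, _ = sm.generate_cohort(params, n=20_000, seed=3)
design = sm.SurveyDesign()

exposed = cohort[cohort["sae_lifetime"] == 1]
unexposed = cohort[cohort["sae_lifetime"] == 0]

a = sm.weighted_prevalence(exposed, "depression", design)
b = sm.weighted_prevalence(unexposed, "depression", design)
print(f"depression | exposed   : {100 * a.point:.1f}% "
      f"[{100 * a.ci_low:.1f}, {100 * a.ci_high:.1f}]  (n={a.n_unweighted})")
print(f"depression | unexposed : {100 * b.point:.1f}% "
      f"[{100 * b.ci_low:.1f}, {100 * b.ci_high:.1f}]  (n={b.n_unweighted})")
print(f"CIs disjoint (flagged as different): {sm.ci_overlap_flag(a, b)}")

print()
table = sm.prevalence_table(
    cohort, {"age_group": list(sm.cohort.AGE_LEVELS),
             "sae_lifetime": None, "depression": None}, design)
print(table.to_string(index=False, float_format="%.1f"))
# 'percent' is the weighted prevalence; n_unweighted counts records in the
# level, as survey tables conventionally report.
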