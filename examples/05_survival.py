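"""Survival analysis of a gene: KM curves, log-rank test and Cox HR.

Simulates a cohort in which subjects with high expression of a gene have
twice the event hazard, then recovers that hazard ratio from the data.
"""

from coexmeta.simulate import gen_survival_cohort
from coexmeta.survival import gene_survival_report

cohort = gen_survival_cohort(n=600, true_hr=2.0, censor_rate=0.25, seed=11)
report = gene_survival_report("DEMO_GENE", cohort.data["expression"], cohort)

print(f"gene {report.gene}: {report.n_high} high vs {report.n_low} low "
      "(median split)")
print(f"hazard ratio = {report.hazard_ratio:.3f} "
      f"(95% CI {report.ci_lower:.3f}-{report.ci_upper:.3f}; true 2.0)")
print(f"log-rank chi2 = {report.logrank_chi2:.2f}, p = {report.logrank_p:.2e}")
print("\nKaplan-Meier survival at the first event times (high group):")
print(report.km_high.head(5).to_string())
# An HR near 2 with a CI excluding 1 and a tiny log-rank p reproduces the
# planted association between expression level and survival.
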