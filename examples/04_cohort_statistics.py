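"""Simulate a full cohort and run the group-statistics battery.

Samples 51 tumor and 57 healthy subjects from the group parameter
distributions, then prints the group-comparison table, the ROC summary,
and the Friedman test of the per-b ADC decline.
"""

from ivimdwi.phantom import CohortSpec, sample_cohort_table
from ivimdwi.stats import friedman_report, table2_report, table3_report

table = sample_cohort_table(CohortSpec(seed=42))
print(f"cohort: {len(table)} subjects "
      f"({(table.group == 'cancer').sum()} cancer, "
      f"{(table.group == 'healthy').sum()} healthy)\n")

t2 = table2_report(table)
print("group comparison (means on the x10^-3 mm^2/s scale; f is a fraction):")
print(t2.round(4).to_string(index=False))

t3 = table3_report(table)
print("\nROC analysis (lower value => cancer; Youden-optimal cutoffs):")
print(t3.round(3).to_string(index=False))

fr, family = friedman_report(table, "cancer")
print(
    f"\nFriedman across b (cancer): chi2={fr.statistic:.1f}, p={fr.p_value:.2e};"
    f" {family.n_pairs} post-hoc pairs at corrected threshold"
    f" {family.corrected_threshold:.4f},"
    f" {len(family.significant_pairs)} significant"
)
print(
    "\nSignificantly lower tumor values on the perfusion-sensitive maps and"
    " the overwhelming Friedman decline mirror the structure the generator"
    " builds in; attribute strata (not shown) are null by construction."
)
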