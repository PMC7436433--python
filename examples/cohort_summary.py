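"""Summarise birth-year cohorts: per-cohort and total diagnosis percentages.

The shipped table lists births and ever-diagnosed counts per birth year;
the Total row aggregates counts before dividing, so it is the overall
prevalence among all births, not an average of yearly rates.
"""

from curemix import cohort_summary, load_cohort_csv

table = load_cohort_csv("fixtures/table1_cohorts.csv")
out = cohort_summary(table)
print(out.to_string(index=False))
print(f"\nOverall prevalence: {out.iloc[-1]['percent']}% "
      f"({out.iloc[-1]['diagnoses']} of {out.iloc[-1]['births']} children)")
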