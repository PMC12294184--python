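"""Diagnostic-yield arithmetic over the packaged variant table.

Loads the packaged digitization of the cohort's variant findings
(24 patients from 20 families) and recomputes the molecular diagnostic
yield, the per-gene family fractions and the novel-variant count.
"""

from enamelmetrics import cohort_summary, packaged_cohort

records = packaged_cohort()
summary = cohort_summary(records, n_patients=24, n_families=20)

print(f"patients: {summary.n_patients}, families: {summary.n_families}")
print(f"diagnostic yield: {100 * summary.dcv_patient_fraction:.1f}% of patients "
      f"carry a conclusive (pathogenic / likely pathogenic) variant")
print(f"unresolved / non-conclusive: {100 * summary.non_conclusive_fraction:.1f}%")
print("families with a conclusive variant, by gene:")
for gene, frac in sorted(summary.gene_family_fractions.items(),
                         key=lambda kv: -kv[1]):
    print(f"  {gene:<7} {100 * frac:.0f}% of families")
print(f"novel conclusive variants (deduplicated by gene + cDNA change): "
      f"{summary.n_novel_dcv}")
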