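"""Cohort statistics at the study conditions.

Simulates 110 women with the default quadrant density distribution and
tumor-location probabilities, then prints the per-quadrant summary table,
the odds of tumor location with 95% limits, the rank cross-tab for dense
area, and the bilateral percent-density correlation.
"""

import mammoquad as mq
import mammoquad.report as report

records = mq.generate_cohort(mq.CohortSpec(n_women=110, seed=7))

t1 = report.table1(records)
print("Per-quadrant BA / DA / PD of the normal breast (mean +- SD):")
print(t1[["quadrant", "BA_display", "DA_display", "PD_display"]]
      .to_string(index=False))

print("\nOdds of tumor location per quadrant (95% Wald limits):")
print(report.odds_table(records=records)[["quadrant", "n_tumors", "display"]]
      .to_string(index=False))

res = mq.proportions_difference_test(
    [sum(r.tumor_quadrant == q for r in records) for q in mq.QUADRANTS])
print(f"\nScore test of equal location probabilities: "
      f"X2 = {res['statistic']:.1f} (df = 3), p = {res['p_value']:.2e}")

ct = mq.build_rank_crosstab(records, "DA")
print("\nDense-area rank of the tumor quadrant (rows: tumor group):")
print(ct.to_dataframe().to_string())

sym = mq.bilateral_symmetry(records)
print(f"\nBilateral PD correlation over non-tumor quadrants: "
      f"r = {sym['r']:.3f} ({sym['n_pairs']} pairs)")
print("An r near 0.90 reflects the generator's bilateral-symmetry "
      "assumption; the UO row concentrating at rank 1 mirrors the larger "
      "dense area the quadrant division assigns to the upper-outer region.")
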