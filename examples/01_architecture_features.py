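"""Measure 3'ss architecture features on a small synthetic cohort.

Generates 20 exons per group with planted AGEZ lengths (up 70 nt, down
40 nt), then measures the AG exclusion zone, the best-scoring branch
point and its polypyrimidine tract for each region, and compares the
groups with a Welch t-test.
"""

import numpy as np

from acceptorkit import (best_branch_point, compare_feature, find_agez,
                         ppt_for_branch_point)
from acceptorkit.synthetic_data import default_cohort_config, generate_cohort

cohort = generate_cohort(default_cohort_config(seed=1, n_per_group=20))

print("exon_id        group  AGEZ  BP_offset  BP_score  PPT_len")
for region in cohort.regions[:6]:
    agez = find_agez(region)
    bp = best_branch_point(region)
    ppt = ppt_for_branch_point(region, bp)
    print(f"{region.exon_id:14s} {region.group:6s} {agez.agez_length:4d} "
          f"{bp.bp_offset:9d} {bp.score:9.2f} {ppt.ppt_length:8d}")

agez = {g: [find_agez(r).agez_length for r in cohort.regions_by_group(g)]
        for g in ("up", "down")}
res = compare_feature(agez["up"], agez["down"], "t")
print(f"\nmean AGEZ: up {np.mean(agez['up']):.1f} nt, "
      f"down {np.mean(agez['down']):.1f} nt")
print(f"Welch t = {res.statistic:.2f}, p = {res.p:.2g}")
print("\nA longer AG exclusion zone upstream of upregulated exons is the "
      "architecture signature\nthe pipeline is built to detect; the t-test "
      "shows the planted contrast is recovered.")
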