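"""Equilibrium single-strandedness (PU) and the delta-PU contrast.

Folds one hairpin-containing window exactly with the McCaskill-style
partition function, then generates a structure-contrast cohort (hairpin
planted upstream of "down" exons only) and computes the positional
delta-PU statistic with Wilcoxon tests.
"""

import numpy as np

from acceptorkit import delta_pu, partition_function
from acceptorkit.synthetic_data import (generate_cohort,
                                        structure_cohort_config)

# a 6-bp stem with a 4-nt loop: stem positions have low unpaired probability
seq = "UUUGGGGGGAAAACCCCCCUUU"
pu = partition_function(seq).unpaired_probabilities()
print("pos base PU")
for i, (b, v) in enumerate(zip(seq, pu)):
    marker = " <- stem" if v < 0.5 else ""
    print(f"{i:3d}  {b}  {v:.3f}{marker}")

cohort = generate_cohort(structure_cohort_config(seed=2, n_per_group=30))
res = delta_pu(cohort.regions_by_group("up"),
               cohort.regions_by_group("down"), flank=0)
span = [o for o in res.offsets if -50 <= o <= -25]
mean_delta = np.mean([res.delta[o] for o in span])
n_sig = sum(res.p.get(o, 1.0) < 0.05 for o in span)
print(f"\ndelta-PU over offsets -50..-25: mean {mean_delta:+.3f}, "
      f"{n_sig}/{len(span)} positions with p < 0.05")
print("\nPositive delta-PU means upregulated 3'ss are more single-stranded "
      "than downregulated ones\nacross the planted span - the positional "
      "structure contrast the statistic is designed to expose.")
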