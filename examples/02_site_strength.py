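"""Intrinsic splice-site strength and the site-pair preference test.

Trains a frequency-matrix (log-odds) model on aligned branch-point 7-mers,
scores candidate sequences in bits, and runs the exact binomial test on a
set of competing 3'ss score pairs in which 51 of 138 promoted sites are
the stronger ones.
"""

from acceptorkit import score_site, site_pair_preference, train_site_model

sites = ["UACUAAC", "CACUAAC", "UGCUAAC", "UUCUAAC", "CUCUAAC"]
model = train_site_model(sites, site_type="bp", pseudocount=0.5)

for seq in ("UACUAAC", "CACUGAC", "GGGGGGG"):
    print(f"score({seq}) = {score_site(seq, model):7.2f} bits")

# 51 of 138 promoted sites stronger than their competitors
pairs = [(1.0, 0.0)] * 51 + [(0.0, 1.0)] * 87
n_stronger, n_ties, n_total, p = site_pair_preference(pairs)
print(f"\n{n_stronger}/{n_total} promoted sites stronger "
      f"({100 * n_stronger / n_total:.0f}%), "
      f"exact two-tail binomial p = {p:.3f}")
print("\nA minority of promoted sites being intrinsically stronger (p < "
      "0.05 against a 50:50 null)\nmeans site choice is not explained by "
      "splice-site strength alone.")
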