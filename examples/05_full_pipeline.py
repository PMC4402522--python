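"""Run every pipeline stage end to end and show the statistics ledger.

Writes features.tsv, comparisons.tsv, pu_profile.tsv, delta_pu.tsv,
apa_events.tsv and a manifest into ./example_output, using a synthetic
cohort of 15 exons per group.
"""

from pathlib import Path

from acceptorkit import RunConfig, run_all

out = Path("example_output")
results = run_all(RunConfig(outdir=out, seed=8, n_per_group=15))

print("group comparisons (architecture stage):")
for cid, comp in results["architecture"]["comparisons"].items():
    print(f"  {cid:28s} {comp.test:8s} stat={comp.statistic:8.3f} "
          f"p={comp.p:.3g}")

delta = results["structure"]["delta"]
starred = [o for o in delta.offsets if delta.star.get(o)]
print(f"\nstructure stage: {len(starred)} offsets starred at p < 0.05")
print(f"apa stage tallies: {results['apa']['tallies']}")
print(f"\ntables written to {out}/ -- every constant used is echoed in "
      f"{out}/manifest.txt,\nso rerunning with the same seed reproduces "
      "the tables byte for byte.")
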