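"""Generate a synthetic tumor cohort and inspect its ground truth.

The simulator plants copy-number event patterns (isochromosome 1q,
BFB-like partial gain, inverted duplication, arm gains, multi-chromosome
gains, 11p CN-LOH), the SVs that produced them, somatic SNVs, and
negative-binomial expression counts with four planted expression clusters.
"""

from collections import Counter

from wtint.simulate import CohortConfig, simulate_cohort, write_cohort

cfg = CohortConfig(seed=1, n_tumors=22)
cohort = simulate_cohort(cfg)

print(f"cohort of {cfg.n_tumors} tumors, {len(cohort.annotation.genes)} genes, "
      f"{len(cohort.annotation.chromosomes)} chromosomes")
print("planted CN patterns:", dict(Counter(t.pattern for t in cohort.truth.tumors.values())))
print("planted expression clusters:",
      dict(Counter(t.cluster for t in cohort.truth.tumors.values())))
mechs = cohort.truth.mechanisms()
print(f"{len(mechs)} tumors carry a 1q gain; planted mechanisms: {sorted(set(mechs.values()))}")

write_cohort(cohort, "example_cohort")
print("wrote annotation/, cn_segments.tsv, sv/*.vcf, snvs.tsv, counts.tsv, truth.json "
      "under example_cohort/")
# The truth record lets every downstream result be scored against what was planted.
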