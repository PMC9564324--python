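"""Consensus SV calling: support filter, population filter, cross-caller merge.

Three noisy simulated callers observe the same planted SVs with breakpoint
jitter, false positives and germline leakage from a population database.
The chain keeps calls with >= 7 reads, removes population matches at > 90%
reciprocal overlap, merges across callers at >= 50% reciprocal overlap
requiring >= 2 tools, and keeps consensus events with allele fraction > 0.1.
"""

from wtint.simulate import CohortConfig, simulate_cohort
from wtint.sv import filter_allele_fraction, filter_population, filter_support, merge_callers

cohort = simulate_cohort(CohortConfig(seed=2, n_tumors=4, n_genes=60))
sample = cohort.samples[0]
callsets = cohort.sv_callsets[sample]

filtered = {}
for caller, calls in callsets.items():
    after_support = filter_support(calls, min_reads=7)
    after_pop = filter_population(after_support, cohort.popdb, ro_threshold=0.9)
    filtered[caller] = after_pop
    print(f"{caller}: {len(calls)} raw -> {len(after_support)} with >=7 reads "
          f"-> {len(after_pop)} after population filter")

merged = merge_callers(filtered, ro_threshold=0.5, min_callers=2)
final = filter_allele_fraction(merged, threshold=0.1)
print(f"merged across callers: {len(merged)} consensus SVs; {len(final)} with AF > 0.1")

truth = cohort.truth.tumors[sample].true_svs
recovered = sum(
    any(m.svtype == t.svtype and m.chrom == t.chrom and abs(m.start - t.start) < 5000
        for m in final)
    for t in truth
)
print(f"planted somatic SVs recovered: {recovered}/{len(truth)}")
# Single-caller artifacts and population variants are gone; the survivors are
# the planted somatic events, each backed by >= 2 callers.
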