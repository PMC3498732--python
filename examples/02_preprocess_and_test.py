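"""Preprocess a simulated 22-array dataset and test for growth-rate-
dependent expression.

Generates the combined chemostat + retentostat design (9 conditions,
22 arrays, 14% replicate CV), applies the scaling/flooring/filtering
rules, and runs the permutation spline F test against log10(mu).
"""

from nearzero import (
    NoiseSpec,
    TestConfig,
    differential_expression,
    floor_and_filter,
    generate_expression,
    global_scale,
    housekeeping_cv,
    select_orfs,
)

matrix, meta, truth = generate_expression(
    n_genes_per_archetype=60, n_housekeeping=6, n_null=600,
    n_decoy_features=150, noise=NoiseSpec(seed=1),
)
print(f"simulated {matrix.shape[0]} features x {matrix.shape[1]} arrays")

scaled = global_scale(matrix, target=300.0)
floored, removed = floor_and_filter(scaled, floor=12.0, min_max=20.0)
orfs = truth.loc[truth["is_orf"], "gene_id"]
clean = select_orfs(floored, orfs)
print(f"after floor/filter: {floored.shape[0]} genes ({len(removed)} discarded); "
      f"{clean.shape[0]} ORFs retained")

hk = truth.loc[truth["is_housekeeping"], "gene_id"]
cv = housekeeping_cv(clean, [g for g in hk if g in clean.index])
print(f"housekeeping CV range: {cv.min():.3f} - {cv.max():.3f} (all < 0.20 -> "
      "global scaling is safe)")

results = differential_expression(clean, meta, TestConfig(n_permutations=1000, seed=1))
called = results[results.significant]
merged = results.merge(truth, on="gene_id")
sens = (merged.significant & merged.is_responder).sum() / merged.is_responder.sum()
print(f"\n{len(called)} of {len(results)} genes significant at p < 0.01 "
      f"(sensitivity vs planted truth: {sens:.2f})")
print(f"smallest q-value among calls: {called.q.min():.2e}")

# Genes whose expression tracks growth rate get small permutation
# p-values; the q-values estimate the false-discovery rate of the list.
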