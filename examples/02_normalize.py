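"""Normalize a count matrix: filtering, TMM factors, log2-CPM, cyclic loess.

Prints the TMM scaling factors (which absorb composition differences
between libraries) and the number of genes passing the detection filter.
"""
import canalkit as ck

design = ck.generate_design(6, 4, 4, seed=1)
counts, _ = ck.simulate_counts(design, ck.SimParams(n_genes=2000), seed=2)

expr, design_kept, diag = ck.normalize_pipeline(
    counts, design, threshold=1.5,
    min_per_species={"human": 16, "chimpanzee": 16},
    loess=True, iterations=1,
)
print(f"kept {expr.values.shape[0]} of {counts.counts.shape[0]} genes "
      f"(log2 CPM > 1.5 in >= 16 samples per species)")
print(f"reference sample for TMM: {diag.ref_sample}")
print("TMM factors (min / median / max): "
      f"{diag.factors.min():.3f} / {diag.factors.median():.3f} / {diag.factors.max():.3f}")
# Factors near 1 mean the libraries are composition-balanced; the log2-CPM
# matrix carries the cyclic-loess flag in expr.norm_state.
print(f"normalization state: {expr.norm_state}")

combined, reduced = ck.combine_replicates(expr, design_kept)
print(f"after combining technical replicates: {combined.values.shape[1]} "
      f"columns (one per individual x day)")
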