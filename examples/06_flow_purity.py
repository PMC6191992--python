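"""Estimate culture purity from per-cell marker fluorescence.

Simulates 6-marker flow data (pluripotency and endoderm-lineage markers),
clusters cells by k-means on the cell-cell correlation matrix (K = 4, one
cluster per differentiation day) and compares estimated per-sample purity
with the generator's truth.
"""
import canalkit as ck

design = ck.generate_design(2, 2, 4, seed=5)
flow_params = ck.FlowParams(cells_per_sample=400, purity_jitter_sd=0.02)
cells, truth = ck.simulate_flow(design, flow_params, seed=6)
print(f"simulated {len(cells)} cells over {truth.shape[0]} samples")

est = ck.estimate_purity(cells, K=4, per_sample=250, seed=0)
print(f"cluster -> day mapping: {est.cluster_to_day}")

merged = truth.set_index("sample_id").assign(estimated=est.purity)
print("\nper-sample purity (estimated vs true):")
for sid, row in merged.iterrows():
    print(f"  {sid}: {row.estimated:.3f} vs {row.true_purity:.3f}")
err = (merged.estimated - merged.true_purity).abs()
print(f"\nmax absolute composition error: {err.max():.3f} "
      "(well-separated components keep this under 0.05)")
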