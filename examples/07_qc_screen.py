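"""QC: expression PCA and the two-stage technical-factor screen.

Stage 1 finds technical factors predicting the leading expression PCs;
stage 2 asks whether the survivors are confounded with day or species; the
partition test checks whether a factor's variance sits in the
species-by-day interaction.
"""
import numpy as np
import pandas as pd

import canalkit as ck

design = ck.generate_design(6, 4, 4, seed=1)
counts, _ = ck.simulate_counts(design, ck.SimParams(n_genes=1500), seed=2)
expr = ck.log2_cpm(counts, ck.tmm_factors(counts).factors)

pca = ck.pca_qc(expr, design, n_pcs=5)
print("PC associations with the biological variables:")
print(pca.assoc.query("PC in ('PC1', 'PC2')").round(3).to_string(index=False))

rng = np.random.default_rng(3)
factors = pd.DataFrame(
    {
        "rna_concentration": rng.normal(50, 10, len(design)),
        "harvest_density": design.day.to_numpy() * 2.0 + rng.normal(0, 1, len(design)),
        "sequencing_pool": rng.choice(["p1", "p2", "p3"], len(design)),
    },
    index=design.sample_id,
)
stage1 = ck.factor_screen(pca, factors, fdr=0.10)
survivors = sorted(stage1.loc[stage1.significant, "factor"].unique())
print(f"\nstage-1 survivors (predict PCs 1-5 at FDR 10%): {survivors}")

for name in survivors:
    for target in ("day", "species"):
        p = ck.factor_design_association(factors[name], design, target, seed=4)
        print(f"  {name} vs {target}: p = {p:.4g}")
    p_int = ck.interaction_partition_test(factors[name], design)
    print(f"  {name} species-by-day interaction: p = {p_int:.4g}")
# harvest_density tracks day by construction, so it should survive stage 1
# and associate with day but not species in stage 2.
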