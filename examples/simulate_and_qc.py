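"""Generate a synthetic retinal atlas and run per-cell quality control.

The atlas has 8 sender cell types and 6 RGC subclasses (3 high-survival,
3 low-survival) across 4 time points around an optic nerve injury.
"""

import retinacomm as rc

cfg = rc.default_config(seed=0, n_planted=5, effect_size=4.0)
adata, truth = rc.generate_atlas(cfg)
print(f"atlas: {adata.n_obs} cells x {adata.n_vars} genes, "
      f"{adata.obs['timepoint'].nunique()} time points")

rc.compute_qc_metrics(adata)
print(adata.obs[["n_umi", "n_gene", "mito_rate", "log10_genes_per_umi"]]
      .describe().loc[["mean", "min", "max"]].round(3))

kept = rc.qc_filter(adata, rc.QC_PRESETS["whole_retina"])
kept = rc.gene_filter(kept, min_cells=5)
print(f"after QC: {kept.n_obs} cells ({kept.n_obs / adata.n_obs:.1%}), "
      f"{kept.n_vars} genes")

# marker-based typing against the generator's marker map
rc.annotate_groups(kept)
rc.assign_cell_types(kept, truth["markers"])
acc = (kept.obs["assigned_type"] == kept.obs["comm_group"]).mean()
print(f"marker-based type assignment agrees with ground truth for {acc:.1%} of cells")
# Cells removed here are mostly the simulated high-mitochondrial subset
# plus a few low-complexity libraries; the assignment accuracy shows the
# marker structure is strong enough to type cells without clustering.
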