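# retinacomm

Intercellular-communication analysis for retinal injury: which signals
from other retinal cells keep retinal ganglion cells (RGCs) alive after
optic nerve damage?

RGC subclasses differ sharply in how well they survive an optic nerve
crush — intrinsically photosensitive RGCs (ipRGCs), αRGCs and Gpr88⁺ RGCs
are resilient, most others die.  `retinacomm` implements the
communication analysis that exploits this contrast: it scores
ligand–receptor interactions from every retinal cell type to every RGC
subclass across an injury time course, and nominates as *neuroprotective*
the interactions that are systematically stronger toward the subclasses
that survive.

## The method

For a ligand–receptor pair (L, R), a sender cell group *s*, a receiver
group *r* and a time point *t*, the interaction score is

    S_LR(s, r, t) = min(1, s0 · (1 + β · max_back))
    s0 = sqrt( ℓ(s, t) · ρ(r, t) )

where ℓ and ρ are the mean normalized (counts-per-10k, log1p) expressions
of the ligand in the sender and the receptor in the receiver, each
min–max scaled to [0, 1] per gene across all (group, time point) means;
`max_back` is the strongest base score among *feedback loops* — back
pairs (L₂, R₂) such that the receiver's active signaling/regulatory
network carries a short directed path R → … → L₂ and R₂ is detected on
the sender.  Candidate pairs must have both genes detected in ≥ 10 % of
their group's cells and reach S_LR ≥ 0.5 at some time point.

The differential statistic contrasts receiver survival classes:

    D_SLR = mean over high-survival subclasses of max_t S_LR
          − mean over low-survival  subclasses of max_t S_LR

D_SLR > 0.25 calls the pair **protective**, D_SLR < −0.25 **depleted**.
Protective pairs are further classified **preset** (high-vs-low advantage
already present before injury) or **induced** (appearing only after),
and trajectories are screened for variability (fold change > 1.2 between
any two time points) and clustered into temporal shape groups.

Supporting stages: per-cell QC (nUMI, nGene, mitochondrial rate,
log10 nGene/log10 nUMI, with literature threshold presets), marker-based
cell typing, survival-normalized subclass composition, and RNAscope
dot quantification (background-corrected per-dot intensity and
bulk-intensity dot counting).

Everything runs end to end on a built-in synthetic atlas generator that
plants known protective pairs, feedback loops and dynamics, so every
stage is testable against ground truth without any data download.

## Worked example

```python
import retinacomm as rc

cfg = rc.default_config(seed=0, n_planted=5, effect_size=4.0)
adata, truth = rc.generate_atlas(cfg)          # 3360 cells x 1200 genes
rc.compute_qc_metrics(adata)
adata = rc.qc_filter(adata, rc.QC_PRESETS["whole_retina"])

lr = rc.LRDatabase.from_frame(rc.lr_table(truth))
table = rc.score_interactions(
    adata, lr,
    senders=list(cfg.sender_types),
    receivers=[name for name, _ in cfg.receiver_subclasses],
)
qualified = rc.qualify_pairs_for_differential(table)
diff = rc.protective_table(qualified)
print(rc.aggregate_nonredundant(diff, top_n=47).head().round(3))
```

prints (abridged):

```
ligand receptor                 senders  n_senders  best_dslr
 ligP1    recP1  AmacrineGABA;...;Photoreceptor      6      0.542
 ligP5    recP5  AmacrineGABA;...;Photoreceptor      7      0.533
 ligP2    recP2  AmacrineGABA;...;Photoreceptor      7      0.503
 ligP4    recP4  AmacrineGABA;...;MullerGlia         5      0.484
 ligP3    recP3  Bipolar;...;Microglia               4      0.453
```

All five planted protective pairs top the ranked list: `best_dslr` is the
largest high-vs-low survival score difference across senders, and
`n_senders` counts the cell types from which the pair is called
protective.  The `examples/` directory has one short script per
capability (QC, differential calls, feedback loops, dynamics,
composition, dot quantification).

A full run — QC → scoring → filtering → differential → dynamics →
aggregation, with a manifest of parameter values and output hashes — is
one call: `rc.run_pipeline(rc.PipelineConfig(seed=0), "out/")`.

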