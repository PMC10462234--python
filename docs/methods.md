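# Methods

## Problem setting

After an optic nerve crush, retinal ganglion cell (RGC) subclasses die at
very different rates.  Interactions that are systematically stronger from
the rest of the retina toward the resilient subclasses (ipRGC, αRGC,
Gpr88RGC) than toward the vulnerable ones are candidate neuroprotective
signals.  `retinacomm` turns that contrast into a score, a differential
statistic, and a set of dynamic classifications, and ships a synthetic
data generator that makes the whole chain testable against planted
ground truth.

## Interaction score

Expression is normalized to counts-per-10k and log1p-transformed; all
group statistics are means of this quantity over the cells of one
(group, time point) stratum, where a "group" is a sender cell type or an
RGC subclass.

The base score for pair (L, R), sender *s*, receiver *r*, time *t* is
the geometric mean of the ligand's and receptor's min–max-scaled group
means, the scaling taken per gene across every (group, time point) mean
in the dataset.  This makes 1.0 mean "both ends at their dataset-wide
maximum" and keeps scores in [0, 1], so the downstream 0.5 cutoff is a
relative-strength criterion.  The geometric mean was chosen over the
product (too harsh on asymmetric pairs) and the arithmetic mean (nonzero
when one end is absent): a pair with an absent ligand scores exactly 0.

Feedback loops multiply the base score by (1 + β·b), capped at 1, where
b aggregates the base scores of back pairs that close a loop (reversed
direction, same time point) and β defaults to 0.5.  Aggregation over
multiple loops uses the maximum — a single strong answer is evidence of
reciprocity; summing would reward network density rather than strength.
The aggregation is a recorded parameter (`ScoringParams.loop_combine`).

A back pair (L₂, R₂) closes a loop on forward pair (L, R) when the
receiver's *active subgraph* (edges of the signaling/regulatory network
whose endpoint genes both reach ≥ 10 % detection in that group) carries
a directed path R → … → L₂ of length ≤ 4, and R₂ is detected on the
sender.  The path bound of 4 admits the receptor → signaling →
transcription factor → ligand relays that motivate the loop concept
while keeping the search bounded.  A sender-side return path R₂ → … → L
is recorded as supplementary evidence when present but never required.
Witness paths are the shortest, tie-broken lexicographically, for
determinism.  When only active subgraphs (not an explicit detected-gene
set) are supplied, sender detection of R₂ falls back to node membership
in the sender's subgraph.

## Filters and overall score

A (sender, receiver, pair) key survives iff both genes are detected in at
least 10 % of their group's cells (evaluated as a max over time points,
consistent with the score criterion below) and max-over-time S_LR ≥ 0.5
— "no less than", so the boundary keeps the pair.  The overall strength
between two groups at one time point is the plain sum of surviving
scores.

## Differential statistic

For each (sender, pair), every receiver subclass contributes its maximum
S_LR over all four time points (including the pre-injury one, matching
the statistic's definition as a max over time points); D_SLR is the mean
of those maxima over the high-survival set minus the mean over the
low-survival set.  Calls use strict cutoffs: protective above 0.25,
depleted below −0.25, ties neutral.  D_SLR is antisymmetric under
swapping the subclass sets by construction.

The per-receiver filter can drop individual subclasses and would leave
D_SLR unevaluable, so the differential stage qualifies a (sender, pair)
when it passes the filter toward *at least one* subclass and then keeps
all subclass rows.  The non-redundant ranked list deduplicates
protective records by pair, keeping the best D_SLR, ranking by it, then
by the number of supporting senders, then lexicographically.

## Dynamics

Variability: a trajectory is variable when the fold change between some
two time points exceeds 1.2.  Scores live on [0, 1] and can be 0, so a
pseudocount of 0.05 (5 % of the scale) enters the ratio; the comparison
is strict.  Shape grouping z-scores each trajectory and clusters with
average-linkage agglomeration on correlation distance, cut at k = 4
groups; correlation distance is undefined for constant trajectories, so
those distances are set to 1 (maximally dissimilar).  The partition is
independent of row order.

Preset vs induced: pre_diff is the high-minus-low subclass difference at
the uninjured time point, post_diff the same difference of per-subclass
maxima over the post-injury points.  A protective pair is *preset* when
pre_diff > δ and *induced* when only post_diff > δ, with δ = 0.25 —
aligned with the differential cutoff so "already different before
injury" means the same magnitude of difference in both analyses.

## QC

Per-cell metrics: nUMI (column sum), nGene (nonzero genes),
mitochondrial rate (mt-prefixed counts / nUMI, case-insensitive,
configurable prefix) and log10(nGene)/log10(nUMI).  Removal rules are
strict inequalities — a cell at exactly a boundary is kept — and cells
with nUMI ≤ 1 have undefined complexity and are removed by any filter.
Four literature presets ship (whole-retina and sorted-RGC scRNA-seq,
sham and injured snRNA-seq); which applies to a dataset is the user's
call.  Genes detected in fewer than 5 cells are dropped.  Cell typing
scores each cell's mean normalized marker expression per type and takes
the argmax, tie-broken lexicographically; clustering and embedding are
deliberately out of scope, so labels come from markers or ground truth.
Cross-dataset compatibility is the Pearson correlation of mean
normalized expression profiles over ≥ 50 shared genes.

## Composition

Post-injury subclass percentages are rescaled by the condition's total
survival rate (an independently measured input, e.g. from
immunostaining; 1.0 for sham), putting all conditions on the pre-injury
scale.  Adjusted values sum to rate × 100 exactly and preserve
between-subclass ratios.

## Dot quantification

Dots are 8-connected components of pixels at or above a detection
threshold (default: background mean + 3 SD; a helper calibrates both
from a user-chosen background region, and the background estimate
otherwise falls back to the mean of sub-threshold pixels).  The per-dot
average subtracts the background over the summed dot area before
dividing by the dot count; bulk dot number divides a region's
background-corrected total intensity by that average.  Both quantities
are linear in above-background signal, so pure background yields zero.
A 3 SD threshold on a noisy image admits occasional single-pixel
excursions; area-filtering such specks is left to the caller.

## Synthetic data

The generator emulates the study design every stage assumes: 8 sender
types (astrocytes, Müller glia, microglia, GABAergic amacrine, bipolar,
horizontal, photoreceptor, endothelial), 6 RGC subclasses (3
high-survival — ipRGC, αRGC, Gpr88RGC — and 3 low), 4 time points (one
sham, three post-injury), 60 cells per group per time point (3360
cells), 1200 genes.  Counts are gamma–Poisson (negative binomial,
dispersion 0.5) with per-gene lognormal baseline abundances (σ = 1),
per-(gene, type) lognormal factors (σ = 0.5) so min–max scaling reflects
genuine type structure rather than pure sampling noise, and per-cell
lognormal library factors (σ = 0.3) targeting ~2000 UMIs — inside the
whole-retina QC window, so default atlases survive default QC.  Each
type gets 5 markers boosted 20×; 5 % of genes are mt-prefixed and 3 % of
cells get an 8× mitochondrial inflation to exercise the QC filter.

Planted interactions boost the ligand in the sender and the receptor in
the targeted survival class by `effect_size`, at all time points
("preset") or post-injury only ("induced").  Planted (and loop-relay)
genes sit on a *flat* cross-type baseline: with random type factors the
realized high-vs-low contrast would be effect_size confounded by
baseline structure, breaking the parameter's meaning as the planted
contrast.  Decoy pairs keep the full type structure, so false-positive
rates are measured against realistically structured noise.  Planted
loops add the receiver-side relay edges (receptor → TF → back ligand)
to the emitted network and express the relay and back-pair genes where
the loop needs them.

Dot images place exactly-area puncta of uniform intensity on a flat
background with a one-pixel guard ring (rejection sampling; bounded
retries), so sums and counts have closed forms.

What the generator does not emulate: doublets, ambient RNA, batch
effects, realistic gene names, spatially varying image background.
Passing tests therefore demonstrate the pipeline's correctness and
sensitivity under a clean negative-binomial world, not robustness to
those artifacts.

## Problem sizes and determinism

Recovery experiments use 20 atlases (5 planted pairs, effect size 4, 50
decoys each) — enough for rate estimates at the granularity the
contracts state while keeping a full run in tens of seconds.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline writes TSVs with a fixed float
format and hashes them into its manifest, so identical configs reproduce
byte-identical outputs.
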