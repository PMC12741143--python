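# Methods

This note documents the models and procedures implemented in `xspecies`, the
defaults they ship with, the synthetic study conditions used by the tests and
the acceptance script, and the limits of what those tests demonstrate.

## Expression model and normalization

All analyses operate on depth-normalized, log-transformed expression
`x_cg = log(1 + c_cg · S / d_c)` with `S = 10,000` counts per cell and
`d_c` the cell's total. The scale constant is the prevailing single-cell
convention; normalization is invariant to per-cell depth and monotone within
a cell, and all-zero cells map to all-zero rows. Counts are held as dense
integer matrices — the package targets desk-scale synthetic data and
downsampled real data, not atlas-scale inputs.

## Ortholog harmonization

Cross-species comparisons need a common gene space, and no single mapping
serves every analysis:

* **Duplicating harmonization** (model input). Every usable ortholog pair
  becomes one unified column: a cyno gene with k human orthologs appears k
  times, a human gene with k cyno orthologs is replicated k times, and
  symbols present in both datasets but absent from the table are kept once
  under the human symbol. No count is ever altered; per-cell totals scale
  only with duplication multiplicity. Column order is sorted; a human name
  occurring in several pairs is disambiguated as `human|source` so
  identifiers stay unique. Duplicates are deliberately *not* re-deduplicated
  before highly-variable-gene selection: the autoencoder's bottleneck
  absorbs input redundancy, whereas dropping orthologs discards signal.
* **1:1 collapse** (differential expression, anything counting unique
  genes). Per target gene the source ortholog with the largest grand total
  of raw counts wins and takes the target name; exact ties break to the
  lexicographically smallest source. "Highest expressed" is operationalized
  as the grand total because it is depth-agnostic and deterministic.
* **Duplicate-then-sum** (cell-cell communication). Each source gene
  contributes its counts to every mapped human name; several sources mapping
  to one name are summed. Mass is conserved for 1:1 genes and multiplied by
  k for 1:k genes — documented and asserted, not hidden.

## Quality control and annotation

Low-quality cells are flagged per sample (replicate x timepoint) when
`log1p(genes detected)` or `log1p(total counts)` leaves `median ± 3·MAD`
(unscaled MAD), or when the mitochondrial fraction exceeds the per-species
threshold. The shipped per-species defaults reproduce the source protocol's
printed values (0.0015 for cyno, 0.15 for human); that 100-fold asymmetry is
exposed unresolved, and pipeline runs on the generator override both to 0.15
because the simulator emits human-like mitochondrial content for both
species.

Doublets are scored by an internal kNN scorer: simulated doublets (sums of
random cell pairs, one per real cell) are co-embedded by PCA of the
normalized matrix, and each cell's score is the fraction of simulated
doublets among its 25 nearest neighbors; calls threshold the score at the
(1 − expected rate) quantile, default rate 0.06. External caller tables can
be supplied instead; a vote flags a cell when at least 2 of up to 3 callers
agree. Cluster pruning then removes whole Leiden clusters (kNN graph, k=15,
resolution 7) whose doublet or low-quality fraction exceeds 0.25 — cells
embedded amid many compromised cells are treated as suspect themselves.

Annotation clusters at resolution 4 and assigns each cluster its modal
per-cell input label (ties lexicographic; all-missing clusters become
"unknown"). An intermediate "level 1.5" granularity keeps a fixed list of
fine subtypes (Platelet, NK/CD4/CD8 Proliferating, CD14/CD16 Mono,
Plasmablast, gdT, MAIT, dnT) and falls back to coarse labels otherwise. Sex
is called per replicate from non-PAR Y-marker detection (male when the
fraction of cells with any Y count exceeds 0.2).

## The variational autoencoder

Encoder and decoder are mirrored MLPs with two hidden layers of 800 units,
each followed by batch normalization, leaky ReLU (slope 0.01) and dropout
(p = 0.2); the encoder outputs the posterior mean and log-variance of a
10-dimensional latent Gaussian. Defaults follow the recommended operating
point (latent 10, batch 8, up to 100 epochs, early-stopping patience 25,
at least 1,000 cells per cell-type model); a hyperparameter grid search over
(latent, batch) on a 1,000-cell subsample with an 80/20 split is provided.
The loss is per-element reconstruction MSE on the log-normalized layer plus
a KL term weighted 5e-5 (exposed; the source protocol does not state its
loss weighting) optimized with Adam at 1e-3. A `linear` decoder mode
replaces the decoder by a single affine map for interpretability at the cost
of capacity. The network is implemented directly on numpy with explicit
backpropagation; training is bit-reproducible from the config seed
(initialization, shuffling, dropout masks, reparameterization draws).
Inference-time encoding returns the posterior mean with batch-norm running
statistics and no dropout, so encode/decode are deterministic. Models refuse
inputs whose gene set differs from the training genes.

Highly variable genes are selected per species as the top-n by normalized
dispersion (variance/mean of log-normalized expression, z-scored within 20
mean-quantile bins), and the per-species selections are unioned.

## Shifts, humanization and evaluation

Shift vectors are differences of latent group means. Humanization encodes
source cells, adds the species shift estimated on training data, and decodes
— never retraining on the target. Generalization is evaluated under two
splits: by replicate (whole individuals held out) and random 50%; the
readout is the Spearman correlation of per-gene mean expression between
humanized (or raw) cyno cells and human cells on the held-out side, with
genes of zero mean in the human reference excluded. Trajectory geometry
reports raw cosine in [−1, 1] plus a rescaled (1+cos)/2 value, magnitudes,
and a planar arrow layout including the maximal-difference reference arrow
(human magnitude at 180°).

## Feature importance

One gene at a time, every cell's value moves toward its species-specific
mean with the step capped at alpha x species sd (alpha = 1 by default):
`x' = x + clip(mu_gs − x, −alpha·sd_gs, +alpha·sd_gs)`. Importance is the
mean Euclidean latent displacement. The cap rule is one consistent reading
of "adjusting the magnitude according to the species-specific variance": it
is bounded, sign-correct and a no-op for cells already at their species
mean.

A structural property of this heuristic, confirmed on planted-truth data:
because the perturbation moves cells within their own species, it probes the
directions a gene varies *inside* the dataset. Genes driving the temporal
response score high (their deviations from the species mean carry latent
information), whereas genes whose only signal is a constant cross-species
offset score near the noise floor — a converged autoencoder learns to ignore
their within-species fluctuations. Importance rankings should therefore be
read as condition-responsiveness, which is also what the companion
comparison against DGE rankings (Spearman rho per cell type/condition,
aggregated by an exact two-sided binomial sign test) measures.

## DGE and pathway statistics

Genes enter testing when detected in ≥ 70% of cells of at least one compared
group (all-zero genes never pass); cell types qualify with ≥ 5 cells per
timepoint in every replicate. The default engine is the two-sided Wilcoxon
rank-sum test on the normalized layer — the same test the source protocol
uses for cluster markers — with log2 fold changes of depth-scaled means
(pseudocount 1) and Benjamini-Hochberg FDR; a per-gene NB-GLM
likelihood-ratio option with log-library offsets exists, treating cells as
units (pseudo-sample aggregation is out of scope and the caveat applies to
both engines). Externally computed tables in the same schema plug into all
downstream statistics.

The regulated-transcriptome fraction is 1 − pi0 with Storey's estimator:
pi0(lambda) over a 0.05..0.95 grid, smoothed by a weighted cubic spline
(weights ~ sqrt(1 − lambda), stabilizing the tail variance which grows like
1/(1 − lambda)) and evaluated at the largest lambda, clipped to [0, 1].

Cross-species overlap intersects significant genes at FDR ≤ 20% on the 1:1
collapsed space; the same-direction fraction among shared genes is tested
against 0.5 by a chi-square one-sample proportion test with continuity
correction (exact binomial by flag). Foregrounds are the top 200 significant
genes by |logFC| (ties: smaller p, then gene id). Enrichment is a one-sided
Fisher exact test per pathway against the background of tested genes, with
BH across pathways, an FDR ≤ 5% and ≥ 2-hit filter, Haldane-Anscombe 0.5
correction for degenerate odds ratios, and — among pathways with identical
hit sets — retention of the highest odds ratio only. Co-enrichment is the
Jaccard index of the two species' hit sets per shared pathway.

## Cell-cell communication

For every ordered cell-type pair and ligand-receptor pair the magnitude is
mean ligand expression in the source times mean receptor expression in the
target; specificity is a label-permutation p with add-one correction
((b+1)/(n_perm+1), default 1,000 permutations). Both statistics become
fractional average ranks (ascending = stronger). Conservation intersects the
two species' significant sets over the full scored background with a
one-sided Fisher test; shared percentages are reported against the union and
against each species. Network edges aggregate surviving interactions per
type pair with weight = sum of log10 magnitude ranks; activity counts a
type's roles as ligand emitter (source) and receptor bearer (target). The
strict 0.001/0.01 rank cuts assume database-scale tables; at the generator's
~100-pair scale the package documents and additionally uses a 0.05 cut —
a scale choice, not a change to the statistic. Multi-subunit complexes are
out of scope (single-gene ligand and receptor only).

## Synthetic study conditions

The generator draws counts as NB(mean = depth_c · p_cg, dispersion 2), where
p_cg is the per-cell softmax of additive log-scale effects: gene baseline
N(0, 1), cell-type marker programs (12 genes per type at +2.2), a species
effect on 30% of genes, per-cell-type temporal programs, replicate
intercepts N(0, 0.15) and planted ligand-receptor boosts (+2 on ligand in
source type, receptor in target type). Depths are lognormal (median 2,500,
sd 0.35 on the log scale). Species effects are sign(u)·(0.5 + |u|) with
u ~ N(0, 0.8): every carrier shifts by at least 0.5 log-units, so planted
species differences are genuine markers rather than noise-floor effects.
Temporal programs touch 150 genes per cell type with per-gene scale 1.2 at
24h and 0.4 of that at 6h (the response is present but weaker early); the
human and cyno 24h vectors are constructed as v_h = u, v_c = t·u +
sqrt(1−t²)·w with w ⊥ u, giving an exactly controlled cross-species cosine
t (default 0.8). The ortholog table covers 81.3% of cyno genes with 10%
1:m/m:1 relations; planted LR genes are always covered, and half the
uncovered genes share their symbol across species. Mitochondrial genes are
a reserved `MT-` block; Y markers use their real names, and the default
replicate sexes mirror the study design (two male monkeys, one male and one
female human). Doublets (5%) are sums of two same-sample cells; low-quality
cells (3%) have non-mito counts shrunk to 5-20% and mito fractions raised to
0.25-0.45. Identical configs produce bit-identical output.

What the generator does **not** emulate: gene-gene correlation beyond the
planted programs (genes are conditionally independent given the cell's
group), batch effects beyond replicate intercepts, ambient RNA, and
continuous differentiation topologies. Passing tests therefore demonstrate
that the statistics recover planted structure under NB noise at realistic
depths — not that they are robust to correlated biological or technical
structure in real tissue.

## Problem sizes and defaults in the test suite

The test suite and the acceptance script run the full protocols at reduced
scale, chosen as the package's own desk-scale conditions: 600 genes
(including reserved blocks), 1-5 cell types of 40-200 cells per
species x replicate x timepoint, VAE hidden widths 64-128, batch 64, up to
40-60 epochs, 300 highly variable genes per species, 500-1,000 permutations.
Per-cell-type VAE minimum cell counts are lowered accordingly in pipeline
configs (the 1,000-cell rule remains the library default). Feature
importance averages three model seeds to reduce encoder noise.

## Known limitations

* The numpy VAE is CPU-bound and sized for thousands, not millions, of
  cells.
* Constant cross-species offsets are structurally under-ranked by the
  perturbation importance heuristic (see above); quartile-level recovery of
  such genes should not be expected from it.
* The Wilcoxon engine treats cells as replicates; with two individuals per
  species, inter-individual variation is partially absorbed by the replicate
  intercepts but not modelled in the test.
* The chi-square proportion test is slightly anticonservative for very small
  shared-gene sets; the exact binomial flag is preferred there.
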