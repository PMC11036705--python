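# Methods

This note records the models, parameter choices, and numerical decisions
behind `gbmspatial`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The generative model

### Reference (single-nucleus) layer

Counts for gene *g* in a cell of type *t* are negative binomial with

    mean  = base_g · markerfold(g, t) · cnvfold(chrom(g), t) · L_c
    var   = mean + mean² / θ

* `base_g ~ Gamma(shape = 2.0, scale = 0.5)` — right-skewed per-gene
  baseline means averaging 1 count/cell, giving library sizes of ~2000 for
  a 2000-gene panel, in the range of nuclei data scaled to the panel size.
* `markerfold` is `marker_fold_change` (default 4) on the
  `marker_genes_per_type` (default 25) genes of the cell's own marker
  program; programs are disjoint across the 8 types (four tumor states
  MES/AC/OPC/NPC-like plus macrophage, oligodendrocyte, endothelial,
  neuron).
* `cnvfold` is a multiplicative fold on every gene of an affected
  chromosome: by default chr7 × 1.5 and chr10 × 0.5 in the tumor states —
  the canonical GBM karyotype.  The simulation is expression-level only:
  a fold is exactly the signal an expression-based caller can see.
* `L_c ~ lognormal(−σ²/2, σ)` with σ = 0.25 is a per-cell size factor with
  mean 1.
* θ (`nb_dispersion`) defaults to 10, a mid-range overdispersion for
  UMI-type counts.
* Ten `MT-`-prefixed pseudo-genes carry `mito_fraction` (default 2%) of
  the counts so the mitochondrial QC rule is exercisable; a handful of
  `RPL*/RPS*` pseudo-genes exercise the ribosomal exclusion; one gene is
  named VEGFA.

Genes are assigned to chromosomes 1–22 proportional to real
protein-coding gene counts per chromosome (gene density is far from
proportional to chromosome length: chr17/19/22 are gene-dense, chr13/18/21
sparse).  This keeps even the smallest chromosome represented by enough
genes for chromosome-level statistics when the panel is scaled down.

### Spatial layer

Spots live on a `grid_shape` array (default 24×24).  Each spot receives
`cells_per_spot` cells (default 10) drawn multinomially from weights
composed of

* its territory state(s): the grid is tiled by quadrant territories, one
  tumor state each by default (`tumor_weight` = 0.65) — this plants the
  tumor-state segregation the colocalization test must detect;
* background non-tumor weights (macrophage 0.10, oligodendrocyte 0.10,
  endothelial 0.05, neuron 0.10);
* macrophage enrichment decaying from the necrotic focus
  (`0.6 · exp(−d/3)`), endothelial and OPC-like enrichment decaying from
  the vessel loci (`0.5 · exp(−d/2)` and `0.35 · exp(−d/2)`) — the
  compositional gradients reported for perinecrotic and perivascular GBM
  niches.

The realized multinomial composition (not the expected weights) is
recorded as the true proportion vector, since it is what the spot's counts
are actually generated from.  Spot counts are sums of per-cell NB draws;
because i.i.d. NB draws with shared dispersion add (Gamma shapes add under
a common scale), the per-(spot, type) block is drawn in one step as
NB(n·μ, n·θ).  VEGFA's mean is multiplied by `1 + (gain − 1)·exp(−d/τ)`
(gain 8, τ = 3 spots), so the center-to-far expression ratio equals the
configured gain and VEGFA retains its baseline far from necrosis.
Optionally, `n_niche_effect_genes` genes receive a per-cell expression
fold of `exp(niche_effect_logfc)` inside the palisading-necrosis niche in
every cell type — a pure expression effect on top of composition, used to
test that adjusted DE recovers per-cell signal.

Gradient regions are eight concentric bands: necrosis, palisade, two
palisade-adjacent layers (1.5-spot increments), generic tumor, and three
vessel-adjacent bands; niches are palisading necrosis (necrosis + palisade
band), perivascular (≤1.2 spots from a vessel), and generic tumor.

### Randomness

Three named substreams are derived deterministically from the seed
(`[seed, 0]` model, `[seed, 1]` reference, `[seed, 2]` spatial), each
consumed in a fixed order.  This keeps every output reproducible from
(seed, config) while letting the spatial stage rerun without replaying the
reference draws.

### What the generator does not emulate

No transcriptome-wide co-expression structure, no ambient RNA or
doublets, no segmentation/histology images, no batch effects, no
platform effect between the reference and spatial modalities, and cell
territories are geometric blocks rather than learned morphology.  Tests
passing on this generator therefore demonstrate statistical correctness
of the estimators under a faithful compositional/count model — not
robustness to the artifacts listed above.

## Analysis choices

* **QC boundaries.** "Fewer than 500 genes" removes cells with <500
  expressed genes; "more than/over 5%" mitochondrial removes strictly
  above 0.05 — a cell at exactly 500 genes and exactly 5% is retained.
* **Normalization.** Reference: `ln(1 + 10⁴·x/total)`.  Spatial: analytic
  Pearson residuals under a rank-1 NB null with fixed θ = 100, clipped to
  ±√n_spots — a closed-form variance-stabilizing transform chosen over a
  regularized per-gene NB regression so that every number is exactly
  reproducible from the formula; θ is configurable.
* **Lineage score denominator** is the mean over *all* genes in the
  (post-QC) matrix, not just signature genes; a flag restricts it to
  detected genes if wanted.  Cluster ties break by declared state order
  and are flagged.  Clustering itself is an input; a k-means-on-PCs
  baseline is provided as plumbing only.
* **CNV.** Window 101 genes, clip ±3, call thresholds ±0.1 — stated,
  configurable defaults; there is no HMM, subclustering or Bayesian
  denoising, targeting only chromosome-arm-scale events.  The moving
  average uses symmetric windows shrunk at chromosome edges and is then
  recentred per (cell, chromosome) to restore the pre-smoothing mean
  exactly (a plain edge-shrunken average is not mean-preserving; the
  recentring makes the conservation property exact by construction).
  Calls contrast *tumor vs pooled normal*: an individual normal type
  compared against a mixed-normal reference shows its own marker program
  as spurious "CNV", which is a known failure mode of expression-based
  callers, not copy number.
* **Deconvolution** is a plain Poisson topic-model MLE on the simplex:
  no platform-effect term, no type-specific dispersion, no doublet mode.
  Profiles are pseudo-bulk sums with a 1e-9 per-gene pseudocount,
  normalized to rates; types under 25 cells are dropped.  EM starts
  uniform (making collinear-profile degeneracies deterministic), stops at
  relative log-likelihood change < 1e-8 or 500 iterations, and asserts
  monotonicity on every run.
* **Colocalization.** BH family = all pairs in one sample's table.  The
  sum-to-one constraint on proportions induces negative correlation a
  priori; the table carries this caveat in its metadata but implements
  the plain Pearson test, as compositional-aware alternatives are out of
  scope.
* **Differential expression.** Per-gene OLS with empirical-Bayes
  moderation: the inverse-chi-square prior (d₀, s₀²) is estimated by the
  method of moments on log s² (digamma/trigamma matching, Newton inverse
  of the trigamma); if the spread of log s² is no larger than the
  chi-square sampling spread, d₀ = ∞ (full shrinkage); if the estimate is
  unusable, moderation falls back to the ordinary t.  Genes whose
  residual variance is zero up to a floating-point floor get p = 1.
  One non-tumor proportion column is dropped for simplex identifiability
  (harmless: with an intercept the remaining columns span the same
  space); degenerate design columns are pruned and logged, and a
  rank-deficient contrast is an error.  α = 0.05 throughout.
* **Gradient analysis.** Region order is the user-declared gradient order
  (necrosis first); a gene enriched in several regions is kept under the
  first.  Ribosomal genes are detected by the RPL/RPS/MRPL/MRPS prefix
  set.  z-scaling uses sd with n−1; constant rows are dropped, not
  imputed.

## Problem sizes

The default study conditions are 2000 genes, 1230 reference cells
(200 per tumor state, 80–150 per normal type) and a 24×24 slide with 10
cells per spot.  The test suite scales these down per property: compact
600–1200-gene panels for simulation-backed unit tests, 200 spots for
deconvolution recovery, 20 seeds for the CNV and gradient recovery rates,
and 1000-spot null matrices for false-signal budgets.  At downscaled
panels the marker programs are also thinned (10 genes per type) so that
marker density per chromosome stays in a realistic range — 200 fold-4
markers among 1200 genes would put several markers on every small
chromosome, a density no real transcriptome exhibits and one that
contaminates chromosome-mean statistics.

## Known limitations

* Absolute logFC values depend on the normalization handed to the DE
  step (Pearson residuals by default); they are comparable within a run,
  not across normalizations, and the VEGFA > 3 niche threshold likewise
  applies to whatever normalized matrix is supplied.
* The deconvolution model ignores platform effects between modalities;
  on real paired data this inflates proportion error relative to the
  synthetic benchmark.
* Chromosomes represented by only a handful of genes are below the CNV
  caller's resolution; calls there are reported but should not be
  trusted (see the gene-density allocation above for why this mostly
  affects strongly downscaled panels).
* Transitional/hybrid tumor states are deliberately not modeled; each
  cluster receives exactly one state.
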