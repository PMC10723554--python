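# Methods

This note documents the models, parameter choices and numerical conventions
behind `plaquescape`, and what the synthetic validation does and does not
establish about real data.

## Data model

A dataset is three aligned tables: per-cell metadata (slice-local coordinates
in µm, segmented volume in µm³, cell type, optional subcluster and region,
genotype, sample, batch), a cells × genes integer count matrix (MatrixMarket
triplet plus gene/cell name lists), and a plaque table (centroid, size,
sample). Genotypes form a closed vocabulary — WT, Trem2R47H, 5xFAD,
Trem2R47H_5xFAD — and unknown labels are hard errors. Each sample maps to
exactly one genotype and batch. Coordinates live in a per-sample frame; no
cross-slice registration is attempted, so every spatial computation is
per-sample. Plaques reported in samples without 5xFAD transgenes raise a
warning rather than an error, because detector false positives are a real
phenomenon the data model must be able to represent.

## Quality control and normalization

Cells with volume > 1800 µm³ or fewer than 50 transcripts are removed;
comparisons are strict, so boundary cells survive. Normalized expression is
library-size scaling to the median post-QC library followed by log1p
(natural log); it is provided for inspection only — all inference works on
counts, through pseudobulk sums or NB offsets, so per-cell depth regression
is not part of this pipeline.

## Plaque geometry

All distances are Euclidean and centroid-to-centroid; "distance to plaque"
means distance to the nearest plaque centroid in the same sample, with +inf
as the sentinel when a sample has no plaques. Nearest-neighbor ties are
broken by lexicographically smallest `cell_id`, making every assignment
deterministic.

Areas of irregular tissue domains come from alpha shapes with the convention
*keep Delaunay triangles whose circumradius is strictly below 1/α*; since the
Delaunay triangles partition the convex hull, the area is the sum of kept
triangle areas. α = 0.015 µm⁻¹ (a 66.7 µm circumradius cutoff) throughout;
α → 0 recovers the convex hull. Fewer than 3 distinct points, collinear
input, or all-rejected triangulations give area 0.

Proximal/distal densities: the proximal band is nearest-plaque distance
< 100 µm, the distal band [100, 500) µm — a cell exactly at 100 µm is distal.
The normalizing area of a band is the alpha shape of *all* cells in the band
(any type); the count is of the target type only. Bands with fewer than
3 cells, or an empty alpha shape, are flagged invalid and excluded from
aggregates. For sparse subtypes the region is instead all cells within 50 µm
of any target-type cell. Plaques are assigned to the region of their nearest
cell (the region label is a property of cells, not of space); regions with
< 3 cells in a sample are excluded from plaque-density reporting.

Two documented simplifications: distances are measured to plaque centroids,
not boundaries (plaque radii at the sizes simulated are ~6 µm, small against
the 100 µm band), and band areas use cells of all types. Detection evaluation
matches predicted to true plaques greedily in ascending centroid distance,
one-to-one, within a configurable radius (default 15 µm); mask-overlap
scoring is out of scope. Rank-sum comparisons use the exact Mann-Whitney
distribution for tie-free groups of ≤ 8, otherwise the normal approximation
with tie correction; an all-tied pooled sample is defined to give p = 1.

## Pseudobulk mixed-effect DE

Counts are summed per (cell type, sample [, stratum]). Two filters precede
modeling: a gene must be detected (count > 0) in ≥ 15 % of the cell type's
cells (computed globally for the type, not per sample; boundary inclusive),
and a pseudobulk row must contain ≥ 50 cells (strict: 49 is dropped, 50
kept). The response is log2(1 + CPM) of the row; CPM normalization makes
log₂ fold changes directly comparable across rows of different depth.

The model is a random-intercept LMM, `y ~ group + (1 | batch)`. The solver
profiles the REML criterion down to a one-dimensional optimization over the
variance ratio λ = σ²_batch/σ²: with the eigendecomposition ZZᵀ = QDQᵀ the
rotated problem is weighted least squares per candidate λ, so each gene costs
about a millisecond and the boundary λ = 0 is handled exactly (it is checked
explicitly and wins ties). The fit is validated against R's lme4 and
statsmodels' MixedLM on non-degenerate designs, where all three agree to
six digits.

Inference uses Wald *t* statistics with *between-within* degrees of freedom:
df = n − p when the batch variance is estimated at zero, df = n − p − (q − 1)
when it is positive (q batches absorb q − 1 degrees of freedom). REML rather
than ML, and a t rather than a normal reference, are deliberate small-sample
choices: at the 8–16 replicate scale of pseudobulk designs a Wald z test is
badly anticonservative (empirical type-I ≈ 0.08–0.10 at nominal 0.05),
whereas the REML/between-within-t combination measures 0.050–0.066 across
batch-variance regimes and 0.0497 on the full 2,000-gene null simulation.
Designs with a single batch fall back to OLS, flagged `ols` in the output.
A degenerate fit with zero residual variance (identical responses) reports
p = 1. BH adjustment is applied across the genes of each contrast, with NaNs
propagated and excluded from the test count.

Significance is |log₂FC| ≥ 0.35 and padj < 0.05 for the genotype and
proximity families. The regional family gates on the *raw* p (padj is also
reported) — region-vs-rest contrasts have many more rows, and this mirrors
the analysis convention the pipeline reproduces. Pairwise genotype DE is run
separately per pair because batches carry unbalanced genotype compositions.

## Continuous distance DE

Per gene, counts of cells within 100 µm of the nearest plaque (5xFAD-carrying
samples only, cells treated as independent) follow an NB GLM with log link,
log library-size offset and distance as covariate. The dispersion
(Var = µ + αµ²) is estimated per gene by alternating between the GLM fit for
the mean and a one-dimensional profile-ML step for α, floored at 1e-8
(≈ Poisson); non-convergent fits fall back to Poisson, flagged. Slopes are
reported as log₂ per 100 µm. Significance is padj < 0.05 with no fold-change
cutoff. Genotype is intentionally not in the model (samples are pooled),
which means genotype-correlated expression can masquerade as distance
dependence; this is a documented caveat of the design being reproduced, not
an oversight. A second caveat is compositional: the offset is the observed
library size, so genes that dominate a small panel partially absorb their own
distance effect — negligible at 300 genes (≈ 2 % attenuation) but visible if
the panel is tiny.

## Spillover filtering

Filters operate on finished DE tables and never alter statistics; each
removal is recorded with a reason (`not-expressed-in-type`, `glial-marker`,
`dam-marker`, `daa-marker`, `spatial-confound`), so |kept| + |ledger| =
|input| always holds and the operations are idempotent and commute. Glial
results are restricted to genes annotated as expressed in the tested type —
the annotation must cover every result gene, and a gap is a hard error.
Neuronal results are purged of glial identity markers and DAM/DAA signature
genes, the gene sets that segmentation spillover pushes into neighboring
somata. The annotation is an explicit input (reference-atlas derivation is
data preparation, not pipeline computation); the generator emits one
consistent with its own panel.

## Subcluster bias

For subcluster s and genotype g, r_{s,g} = n_{s,g}/N_g normalizes away
unequal genotype cell totals, and p_{s,g} = r_{s,g}/Σ r normalizes rows to
1, so 0.25 everywhere is a uniform draw. Classification uses strict
thresholds ("exceeds"): single-genotype enrichment above 0.33, pair
enrichment above 0.60 for the four factor-sharing pairs only ({WT, T},
{5xFAD, T;5xFAD}, {WT, 5xFAD}, {T, T;5xFAD}) — the two diagonal pairs have
no shared genetic factor to attribute enrichment to and are never reported.
Subclusters under 5 % of the cell type are excluded before any labeling;
single-genotype labels shadow pair labels; among multiple triggers the
largest proportion wins. Activation-state proportions per region-sample are
compared between genotypes with the same random-intercept machinery applied
to the per-sample proportions.

## Synthetic data generator

The generator is first-class, tested code, and its defaults encode the study
conditions end to end: 4 genotypes × 4 samples over 3 imaging batches
(matching the scale of a 15-animal, 5-batch study), six 1000 × 1000 µm
rectangular regions, a 300-gene panel, and cell densities a few ×10⁻⁴
cells/µm² split across five major types. Rectangles replace atlas shapes
because downstream analyses consume only region labels and areas.

Cells are independent spatial Poisson processes per (region, type); plaques
are spatial Poisson with intensities of order 10⁻⁵ plaques/µm² (highest in
the corpus callosum analogue), multiplied by genotype factors that are zero
outside 5xFAD carriers and slightly lower in the double mutant. Plaque sizes
are log-normal with mean ≈ 1,000 µm³. Counts are gamma-Poisson (exact NB)
with dispersion 0.3, log-normal library-size factors (σ = 0.35, mean 1),
and per-batch per-gene log-normal factors (σ = 0.2) that give the batch
random effect something real to absorb. Marker genes get high means in their
own type and 0.02 elsewhere; background baselines are log-normal, floored at
0.05 so the derived expression annotation covers them; genes carrying
injected effects are floored at mean 1.0 in their target type, as a designed
panel would ensure for genes of interest.

Injected effects enter the log₂ mean: genotype effects (applied in a listed
genotype set), region effects, proximal effects (< 100 µm of a plaque), and
distance slopes (linear in distance inside the 100 µm window, zero outside
it, in log₂ per 100 µm). DAM/DAA states are Bernoulli with probability
p_max·exp(−d/50 µm) (p_max 0.9 for microglia, 0.6 for astrocytes), and
state membership applies a signature shift (e.g. Itgax +3, Cst7 +3,
P2ry12 −1.5 in DAM). Subcluster labels are drawn per cell with
genotype-dependent weights. Spillover, off by default, adds a binomially
thinned fraction (the configured rate, at most 0.5) of each cell's 3 nearest
neighbors' pre-spillover counts — the simplest mechanism that reproduces
marker bleed between adjacent cell types. The magnitude of real spillover
is not known; 0.1 is used in validation as a clearly visible rate.

Each sample draws from its own RNG stream derived from the master seed and a
hash of the sample id, so adding samples never perturbs existing ones and a
fixed seed reproduces every output byte. The truth log enumerates every
injected effect once, records per-cell states and subclusters, and lists the
state signature genes per cell type — those genes genuinely respond to
plaque distance (and hence genotype) through the state mechanism, so
recovery scoring counts them as state-driven rather than false discoveries.

## Validation design and what it shows

The acceptance experiments (in `plaquescape.validation`, surfaced by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use purpose-built
configurations sized to run in minutes on one CPU: null calibration on a
2,000-gene panel with 4 samples/genotype; FDP on 20 replicates of a 300-gene
panel with 30 injected |log₂FC| = 1 effects; recovery of 20 injected effects
per family at 8 replicates per level; distance-slope recovery over 20
single-sample replicates with ~500–600 cells in the fitting window; and a
spillover experiment at rate 0.1 with strongly expressed glial genes, whose
plaque-driven upregulation bleeds into neurons and produces the marker false
positives the neuronal filter must remove. FDP is measured on the pipeline's
own discovery rule (fold-change gate plus BH); the padj-only FDP is reported
alongside and is slightly above the nominal level (≈ 0.11), reflecting the
small-sample t approximation's tail behavior. Distance-slope accuracy is
assessed on the mean estimate across replicates (each single estimate
carries sampling noise of ±0.19 at 500 NB cells) plus per-replicate sign
agreement.

Passing these tests shows the implementation is correct and calibrated under
the generator's assumptions. Real MERFISH data violate several of them in
ways the simulation deliberately does not model: segmentation errors are
spatially structured rather than k-NN-symmetric, cell placement is clustered
rather than Poisson, region geometry is curved, dispersion varies per gene,
and plaques grow where pathology is worst rather than independently of
cells. The filtering and mixed-model layers exist precisely because of such
violations, but their real-data performance can only be bounded, not proven,
by synthetic recovery.

## Known limitations

- The regional family's raw-p gate trades FDR control for sensitivity,
  mirroring the convention it reproduces; adjusted p-values are reported for
  users who prefer them.
- Compositional normalization (CPM, library-size offsets) lets very strong
  effects in dominant genes slightly attenuate themselves and perturb
  neighbors; with a 300-gene panel the effect is ≈ 2 %.
- Pair-enrichment classification reports a single best label; a subcluster
  enriched in two disjoint pairs simultaneously is not representable.
- `state_region_proportions` treats per-sample proportions as Gaussian in
  the LMM; for regions with very few cells a binomial model would be more
  appropriate.
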