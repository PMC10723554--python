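# plaquescape

Spatial single-cell analysis of gene expression around amyloid-beta plaques.

MERFISH-style spatial transcriptomics measures a targeted gene panel (~300
genes) in hundreds of thousands of individual cells while keeping their tissue
coordinates. In mouse models of Alzheimer's disease (5xFAD, Trem2^R47H, and
the combined line) this makes it possible to ask not just *which* genes change
in *which* cell types, but *where*: how expression in microglia, astrocytes
and neurons depends on distance to the nearest plaque, how cell densities and
activation states redistribute around plaques, and which of those apparent
changes are segmentation artifacts rather than biology.

`plaquescape` implements that analysis as a tested, reusable pipeline:

- **Plaque geometry** — nearest-plaque distances, closest-cell-type
  proportions, plaque density per region, plaque-neuron spacing statistics,
  and detection scoring (precision/recall/F1 by greedy centroid matching).
  Tissue areas are estimated with **alpha shapes**: the union of Delaunay
  triangles with circumradius below 1/α (α = 0.015 µm⁻¹), a concave hull that
  turns a point cloud of cells into an area for density normalization. Cell
  densities are reported proximal (< 100 µm) and distal (100–500 µm) to
  plaques.
- **Pseudobulk mixed-effect differential expression.** Counts are summed per
  (cell type × sample [× stratum]) after two filters — genes detected in
  < 15 % of the cell type's cells are not analyzed, and pseudobulk rows built
  from < 50 cells are dropped. Each gene is modeled as

  `log2(1 + CPM) ~ group + (1 | batch)`

  with a random intercept per imaging batch (profiled REML, Wald *t* tests).
  Three contrast families share this machinery: the four pairwise genotype
  comparisons (5xFAD vs WT, Trem2^R47H;5xFAD vs Trem2^R47H, Trem2^R47H vs
  WT, Trem2^R47H;5xFAD vs 5xFAD), region-vs-rest, and plaque
  proximal-vs-distal. A gene is called significant when |log₂FC| ≥ 0.35 and
  BH-adjusted p < 0.05 (raw p for the regional family).
- **Continuous distance regression** — per-cell negative-binomial GLM with
  log library-size offset and distance-to-plaque as covariate, per-gene ML
  dispersion; effects reported as log₂ per 100 µm, significance by adjusted
  p alone.
- **Annotation-based filtering** of spillover artifacts: glial DE restricted
  to genes annotated as expressed in the type; neuronal DE purged of glial
  identity markers and DAM/DAA (disease-associated microglia/astrocyte)
  signature genes; spatially confounded subcluster markers removed. Every
  removal is written to a ledger.
- **Genotype-bias classification** of subclusters: per-genotype-normalized
  proportions (0.25 = uniform); enriched in a genotype if its proportion
  exceeds 33 %, in an allowed genotype pair if their sum exceeds 60 %;
  subclusters under 5 % of cells excluded.
- **A synthetic-data generator** that emulates the study's structure — four
  genotypes across samples and batches, spatial Poisson cells and plaques
  (plaques only in 5xFAD carriers), NB counts with batch and library-size
  effects, distance-decaying DAM/DAA activation, genotype-biased subclusters,
  k-NN transcript spillover — together with a machine-readable truth log, so
  every stage can be scored against known ground truth.

## Worked example

Run the full pipeline on the bundled study-like synthetic configuration and
score it against the generator's truth log:

```python
import plaquescape as pq
from plaquescape.pipeline import family_summary, recovery_report

out = pq.run_pipeline({}, "out/", seed=1)
truth = pq.TruthLog.from_json("out/data/truth.json")
print(family_summary(recovery_report(truth, "out/")))
```

This simulates 48,454 cells and 1,193 plaques (16 samples, 4 genotypes, 3
batches, 300 genes; 48,344 cells pass QC), runs geometry, all four DE
families, filtering and bias scoring in ~15 s, and prints:

```
            family  n_effects  sensitivity  fdp     rmse      mae
    distance-slope          1          1.0  0.0 0.039626 0.039626
          pairwise          6          1.0  0.0 0.032731 0.030027
proximal_vs_distal          2          1.0  0.0 0.038337 0.036457
          regional          2          1.0  0.0 0.019699 0.019490
```

Every injected effect (|log₂FC| = 1 genotype/region/proximal effects, a −1
log₂/100 µm distance slope) is recovered with the right magnitude
(MAE ≤ 0.04) and no false discoveries beyond the truth- and state-driven
sets. The proximal-vs-distal table for microglia shows both the injected
effects and the emergent DAM biology:

```
 gene    log2fc         padj  significant
 G030  0.975399 6.207446e-09         True   # injected proximal effect (+1)
 G040 -0.577322 6.183567e-07         True   # injected distance slope, seen as proximal-distal shift
 Csf1  0.889014 5.521007e-06         True   # DAM signature
Itgax  1.371152 1.269925e-05         True   # DAM signature
```

and the microglial subcluster bias table classifies the activated subcluster
as amyloid-enriched:

```
 subcluster    WT  Trem2R47H  5xFAD  Trem2R47H_5xFAD  size_fraction        classification
  Micro_act 0.112      0.102  0.394            0.392          0.331        enriched:5xFAD
Micro_homeo 0.318      0.323  0.179            0.180          0.669 enriched:WT+Trem2R47H
```

(`Micro_act` is drawn ~4× more often from 5xFAD-carrying genotypes; 0.25
would be a uniform draw.)

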