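"""Pseudobulk construction and mixed-effect differential expression.

Single-cell counts are aggregated into pseudobulk replicates (cell type x
sample, optionally further split by a stratum such as region or plaque
proximity), then each gene is modeled as

    log2(1 + CPM) ~ group + (1 | batch)

with a random intercept per imaging batch. Three contrast families share this
machinery: pairwise genotype comparisons, region-vs-rest, and plaque
proximal-vs-distal. Fold changes are base-2 per field convention.

Filters applied before modeling:

* genes detected (count > 0) in fewer than 15% of the cell type's cells are
  not analyzed;
* pseudobulk rows built from fewer than 50 cells are dropped.

Significance: |log2FC| >= 0.35 and BH-adjusted p < 0.05 for the genotype and
proximity families; the regional family gates on the raw p (both are reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AMYLOID_GENOTYPES, CountMatrix, de_frame
from .geometry import DISTAL_BAND, PROXIMAL_RADIUS, nearest_plaque_distance
from .mixedlm import fit_random_intercept

MIN_CELLS_PER_ROW = 50
MIN_DETECTION_FRACTION = 0.15
LFC_THRESHOLD = 0.35
ALPHA = 0.05

GENOTYPE_PAIRS = (
    ("5xFAD", "WT"),
    ("Trem2R47H_5xFAD", "Trem2R47H"),
    ("Trem2R47H", "WT"),
    ("Trem2R47H_5xFAD", "5xFAD"),
)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjustment, order-preserving, NaN-aware.

    NaN inputs stay NaN and do not count toward the number of tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


# ---------------------------------------------------------------------------
# Pseudobulk construction
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkMatrix:
    """Summed counts per (cell type, sample [, stratum]) replicate."""
    counts: np.ndarray          # rows x genes, integer
    genes: np.ndarray
    rows: pd.DataFrame          # sample_id, stratum?, genotype, batch_id, n_cells
    cell_type: str

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]


def build_pseudobulk(
    cells: pd.DataFrame,
    cm: CountMatrix,
    cell_type: str,
    strata: pd.Series | None = None,
    min_cells: int = MIN_CELLS_PER_ROW,
    min_detection: float = MIN_DETECTION_FRACTION,
) -> PseudobulkMatrix:
    """Aggregate single-cell counts into pseudobulk replicates for one cell type.

    ``strata``, when given, is aligned to ``cells.index``; cells with a null
    stratum are excluded. The gene detection filter is computed across all
    cells of the type (before any stratification); the ``min_cells`` rule is
    applied per pseudobulk row.
    """
    mask = (cells["cell_type"] == cell_type).to_numpy()
    sub = cells[mask]
    sub_cm = cm.subset_cells(mask)

    if len(sub) == 0:
        warnings.warn(f"no cells of type {cell_type!r}", stacklevel=2)
        return PseudobulkMatrix(np.zeros((0, 0), int), np.array([], object),
                                _empty_rows(strata is not None), cell_type)

    detection = np.asarray((sub_cm.counts > 0).mean(axis=0)).ravel()
    gene_keep = detection >= min_detection
    counts = sub_cm.counts[:, gene_keep]
    genes = sub_cm.gene_names[gene_keep]

    keys = sub["sample_id"].astype(str)
    if strata is not None:
        strat = strata.loc[sub.index]
        ok = strat.notna().to_numpy()
        sub, counts, keys = sub[ok], counts[np.flatnonzero(ok)], keys[ok]
        strat = strat[ok].astype(str)
        key_frame = pd.DataFrame({"sample_id": keys, "stratum": strat})
    else:
        key_frame = pd.DataFrame({"sample_id": keys})

    meta = sub.drop_duplicates("sample_id").set_index("sample_id")[["genotype", "batch_id"]]
    group_cols = list(key_frame.columns)
    codes, uniques = pd.factorize(pd.MultiIndex.from_frame(key_frame), sort=True)

    n_groups = len(uniques)
    indicator = np.zeros((n_groups, len(sub)))
    indicator[codes, np.arange(len(sub))] = 1.0
    summed = np.asarray(indicator @ counts.toarray()).astype(np.int64)
    n_cells = indicator.sum(axis=1).astype(int)

    rows = pd.DataFrame(list(uniques), columns=group_cols)
    rows["n_cells"] = n_cells
    rows["genotype"] = meta.loc[rows["sample_id"], "genotype"].to_numpy()
    rows["batch_id"] = meta.loc[rows["sample_id"], "batch_id"].to_numpy()

    keep = rows["n_cells"].to_numpy() >= min_cells
    rows = rows[keep].reset_index(drop=True)
    summed = summed[keep]
    if len(rows) == 0:
        warnings.warn(
            f"no pseudobulk rows with >= {min_cells} cells for {cell_type!r}",
            stacklevel=2,
        )
    return PseudobulkMatrix(summed, genes, rows, cell_type)


def _empty_rows(with_stratum: bool) -> pd.DataFrame:
    cols = ["sample_id"] + (["stratum"] if with_stratum else []) + ["n_cells", "genotype", "batch_id"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def log2_cpm(counts: np.ndarray) -> np.ndarray:
    """log2(1 + counts-per-million) per pseudobulk row."""
    counts = np.asarray(counts, float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log2(1.0 + counts / totals * 1e6)


# ---------------------------------------------------------------------------
# Mixed-effect contrast
# ---------------------------------------------------------------------------

def lme_contrast(
    pb: PseudobulkMatrix,
    group: pd.Series | np.ndarray,
    levels: tuple[str, str],
    contrast: str,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    significance_on: str = "padj",
) -> pd.DataFrame:
    """Per-gene mixed-model contrast ``levels[0]`` minus ``levels[1]``.

    The response is log2(1 + CPM) of the pseudobulk row; the model has the
    two-level group as fixed effect and the imaging batch as random intercept
    (profiled REML; ordinary least squares when only one batch is present).
    BH adjustment is applied across the genes of this contrast.
    """
    group = np.asarray(group, dtype=object)
    alt, ref = levels
    in_alt = group == alt
    in_ref = group == ref
    used = in_alt | in_ref
    if in_alt.sum() < 2 or in_ref.sum() < 2:
        warnings.warn(
            f"contrast {contrast!r} skipped: fewer than 2 replicates per level "
            f"({alt}: {int(in_alt.sum())}, {ref}: {int(in_ref.sum())})",
            stacklevel=2,
        )
        return de_frame([])
    y_all = log2_cpm(pb.counts[used])
    X = np.column_stack([np.ones(int(used.sum())), in_alt[used].astype(float)])
    batches = pb.rows.loc[used, "batch_id"].to_numpy()
    n = int(used.sum())

    recs = []
    for j, gene in enumerate(pb.genes):
        fit = fit_random_intercept(y_all[:, j], X, batches)
        recs.append({
            "gene": gene, "log2fc": float(fit.coef[1]), "se": float(fit.se[1]),
            "pvalue": float(fit.pvalue[1]), "contrast": contrast, "n": n,
            "method": fit.method,
        })
    res = de_frame(recs)
    res["padj"] = benjamini_hochberg(res["pvalue"].to_numpy())
    gate = res["padj"] if significance_on == "padj" else res["pvalue"]
    res["significant"] = (res["log2fc"].abs() >= lfc_threshold) & (gate < alpha)
    return res


# ---------------------------------------------------------------------------
# Contrast families
# ---------------------------------------------------------------------------

def pairwise_genotype_de(
    cells: pd.DataFrame,
    cm: CountMatrix,
    cell_type: str,
    pair: tuple[str, str],
    **kwargs,
) -> pd.DataFrame:
    """Pseudobulk DE between two genotypes for one cell type (``pair[0]`` vs ``pair[1]``)."""
    mask = cells["genotype"].isin(pair).to_numpy()
    if not mask.any():
        warnings.warn(f"no cells for genotype pair {pair}", stacklevel=2)
        return de_frame([])
    sub = cells[mask]
    pb = build_pseudobulk(sub, cm.subset_cells(mask), cell_type,
                          min_cells=kwargs.pop("min_cells", MIN_CELLS_PER_ROW),
                          min_detection=kwargs.pop("min_detection", MIN_DETECTION_FRACTION))
    if pb.n_rows == 0:
        return de_frame([])
    contrast = f"{cell_type}:{pair[0]}_vs_{pair[1]}"
    return lme_contrast(pb, pb.rows["genotype"], pair, contrast, **kwargs)


def regional_de(
    cells: pd.DataFrame,
    cm: CountMatrix,
    cell_type: str,
    region: str,
    genotype: str | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Region-vs-rest pseudobulk DE for one cell type.

    Pseudobulk rows are (sample, region) combinations; sample-region
    combinations with fewer than 50 cells are excluded by construction.
    Significance gates on the raw p-value (adjusted p is also reported).
    """
    if genotype is not None:
        mask = (cells["genotype"] == genotype).to_numpy()
        cells, cm = cells[mask], cm.subset_cells(mask)
    pb = build_pseudobulk(cells, cm, cell_type, strata=cells["region"],
                          min_cells=kwargs.pop("min_cells", MIN_CELLS_PER_ROW),
                          min_detection=kwargs.pop("min_detection", MIN_DETECTION_FRACTION))
    if pb.n_rows == 0:
        return de_frame([])
    group = np.where(pb.rows["stratum"] == region, region, "rest")
    if (group == region).sum() == 0:
        warnings.warn(f"region {region!r} absent after the 50-cell filter", stacklevel=2)
        return de_frame([])
    tag = f"{genotype}:" if genotype else ""
    contrast = f"{cell_type}:{tag}{region}_vs_rest"
    kwargs.setdefault("significance_on", "pvalue")
    return lme_contrast(pb, group, (region, "rest"), contrast, **kwargs)


def proximal_distal_de(
    cells: pd.DataFrame,
    cm: CountMatrix,
    plaques: pd.DataFrame,
    cell_type: str,
    proximal_radius: float = PROXIMAL_RADIUS,
    distal_band: tuple[float, float] = DISTAL_BAND,
    **kwargs,
) -> pd.DataFrame:
    """Pseudobulk DE of plaque-proximal vs plaque-distal cells of one type.

    Restricted to plaque-bearing (5xFAD-carrying) samples. Proximal means
    nearest-plaque distance < ``proximal_radius``; a cell exactly at the
    boundary is distal. Distal is the half-open band [100, 500).
    """
    has_plaques = set(plaques["sample_id"]) if len(plaques) else set()
    mask = (cells["genotype"].isin(AMYLOID_GENOTYPES)
            & cells["sample_id"].isin(has_plaques)).to_numpy()
    if not mask.any():
        warnings.warn("no plaque-bearing samples for proximity DE", stacklevel=2)
        return de_frame([])
    sub = cells[mask]
    sub_cm = cm.subset_cells(mask)
    dist = nearest_plaque_distance(sub, plaques[plaques["sample_id"].isin(set(sub["sample_id"]))])
    strata = pd.Series(pd.NA, index=sub.index, dtype=object)
    strata[dist < proximal_radius] = "proximal"
    strata[(dist >= distal_band[0]) & (dist < distal_band[1])] = "distal"
    pb = build_pseudobulk(sub, sub_cm, cell_type, strata=strata,
                          min_cells=kwargs.pop("min_cells", MIN_CELLS_PER_ROW),
                          min_detection=kwargs.pop("min_detection", MIN_DETECTION_FRACTION))
    if pb.n_rows == 0:
        return de_frame([])
    contrast = f"{cell_type}:proximal_vs_distal"
    return lme_contrast(pb, pb.rows["stratum"], ("proximal", "distal"), contrast, **kwargs)
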