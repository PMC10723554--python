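"""Spatial computations around amyloid plaques.

Distances are Euclidean, centroid-to-centroid, within a single sample's frame.
Areas of irregular tissue domains are estimated with alpha shapes: the union of
Delaunay triangles whose circumradius is below ``1/alpha``, the concave
generalization of the convex hull used throughout for density normalization
(default ``alpha = 0.015`` per micrometer, i.e. a 66.7 um circumradius cutoff).

Ties in nearest-neighbor queries are broken by lexicographically smallest
``cell_id`` so every result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import Delaunay, cKDTree

DEFAULT_ALPHA = 0.015           # 1/um
PROXIMAL_RADIUS = 100.0         # um
DISTAL_BAND = (100.0, 500.0)    # um
_TIE_EPS = 1e-9


# ---------------------------------------------------------------------------
# Nearest-distance primitives
# ---------------------------------------------------------------------------

def nearest_plaque_distance(cells: pd.DataFrame, plaques: pd.DataFrame) -> pd.Series:
    """Distance from each cell to the nearest plaque centroid in its own sample.

    Returns a float Series aligned to ``cells.index``; cells in samples without
    plaques get ``+inf``.
    """
    extra = sorted(set(plaques["sample_id"]) - set(cells["sample_id"])) if len(plaques) else []
    if extra:
        raise ValueError(f"plaques from samples absent in cell table: {extra}")
    out = pd.Series(np.inf, index=cells.index, dtype=float)
    for sample, grp in cells.groupby("sample_id"):
        pl = plaques[plaques["sample_id"] == sample]
        if pl.empty:
            continue
        tree = cKDTree(pl[["x", "y"]].to_numpy(float))
        d, _ = tree.query(grp[["x", "y"]].to_numpy(float), k=1)
        out.loc[grp.index] = d
    return out


def _nearest_cell(points: np.ndarray, cells: pd.DataFrame) -> np.ndarray:
    """Index (into ``cells``) of the nearest cell to each query point.

    Exact tie-breaking: among cells at the minimal distance (within 1e-9),
    pick the lexicographically smallest cell_id.
    """
    xy = cells[["x", "y"]].to_numpy(float)
    ids = cells["cell_id"].to_numpy(object)
    tree = cKDTree(xy)
    d, idx = tree.query(points, k=1)
    out = np.asarray(idx, dtype=int).copy()
    for i, (pt, di) in enumerate(zip(points, d)):
        cand = tree.query_ball_point(pt, di + _TIE_EPS)
        if len(cand) > 1:
            out[i] = min(cand, key=lambda j: (ids[j],))
    return out


def closest_cell_type_proportions(plaques: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Cell-type proportions of the single closest cell to each plaque.

    For every plaque the nearest cell (same sample) is identified; proportions
    of the resulting cell types are reported per genotype and sum to 1 within
    each genotype.
    """
    if plaques.empty or cells.empty:
        raise ValueError("need at least one plaque and one cell")
    recs = []
    for sample, pl in plaques.groupby("sample_id"):
        sub = cells[cells["sample_id"] == sample].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"sample {sample} has plaques but no cells")
        idx = _nearest_cell(pl[["x", "y"]].to_numpy(float), sub)
        for pid, j in zip(pl["plaque_id"], idx):
            recs.append({
                "plaque_id": pid, "sample_id": sample,
                "genotype": sub.at[j, "genotype"],
                "cell_type": sub.at[j, "cell_type"],
                "cell_id": sub.at[j, "cell_id"],
            })
    closest = pd.DataFrame(recs)
    counts = closest.groupby(["genotype", "cell_type"]).size().rename("n_plaques").reset_index()
    totals = counts.groupby("genotype")["n_plaques"].transform("sum")
    counts["proportion"] = counts["n_plaques"] / totals
    return counts


# ---------------------------------------------------------------------------
# Alpha shapes
# ---------------------------------------------------------------------------

def alpha_shape_area(points: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Area of the alpha shape of a 2-D point set.

    Keeps Delaunay triangles with circumradius strictly below ``1/alpha``
    (``alpha = 0`` keeps everything, recovering the convex hull). Delaunay
    triangles partition the hull, so the union area is the sum of kept
    triangle areas. Fewer than 3 distinct points, collinear input, or all
    triangles rejected give area 0.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.ndim != 2 or pts.shape[0] < 3:
        return 0.0
    try:
        tri = Delaunay(pts)
    except Exception:  # collinear / degenerate input
        return 0.0
    if tri.simplices.size == 0:
        return 0.0
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(a - c, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area > 0, ab * bc * ca / (4.0 * area), np.inf)
    cutoff = np.inf if alpha == 0 else 1.0 / alpha
    return float(area[circumradius < cutoff].sum())


# ---------------------------------------------------------------------------
# Density reports
# ---------------------------------------------------------------------------

@dataclass
class DensityReport:
    """Cell density of one target type proximal and distal to plaques in one sample."""
    sample_id: str
    cell_type: str
    proximal_count: int
    distal_count: int
    proximal_area: float
    distal_area: float
    proximal_density: float     # cells / um^2; NaN when undefined
    distal_density: float
    proximal_valid: bool
    distal_valid: bool


def proximal_distal_density(
    cells: pd.DataFrame,
    plaques: pd.DataFrame,
    target_type: str,
    proximal_radius: float = PROXIMAL_RADIUS,
    distal_band: tuple[float, float] = DISTAL_BAND,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-sample density of ``target_type`` cells near vs far from plaques.

    Band membership uses nearest-plaque distance: proximal is ``< proximal_radius``,
    distal is ``[distal_band[0], distal_band[1])``. The normalizing area in each
    band is the alpha-shape area of *all* cells (any type) in the band; the count
    is restricted to the target type. A band with fewer than 3 cells has no
    defined area and is flagged invalid.
    """
    dist = nearest_plaque_distance(cells, plaques)
    rows = []
    for sample, grp in cells.groupby("sample_id"):
        if plaques[plaques["sample_id"] == sample].empty:
            continue
        d = dist.loc[grp.index].to_numpy()
        prox = d < proximal_radius
        distal = (d >= distal_band[0]) & (d < distal_band[1])
        rec = {"sample_id": sample, "cell_type": target_type}
        for name, mask in (("proximal", prox), ("distal", distal)):
            band = grp[mask]
            count = int((band["cell_type"] == target_type).sum())
            valid = len(band) >= 3
            area = alpha_shape_area(band[["x", "y"]].to_numpy(float), alpha) if valid else 0.0
            valid = valid and area > 0
            rec[f"{name}_count"] = count
            rec[f"{name}_area"] = area
            rec[f"{name}_density"] = count / area if valid else np.nan
            rec[f"{name}_valid"] = valid
        rows.append(rec)
    return pd.DataFrame(rows, columns=[
        "sample_id", "cell_type", "proximal_count", "proximal_area",
        "proximal_density", "proximal_valid", "distal_count", "distal_area",
        "distal_density", "distal_valid",
    ])


def subtype_region_density(
    cells: pd.DataFrame,
    target_type: str,
    radius: float = 50.0,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Density of a sparse cell type within its own 50-um neighborhood region.

    The region for a subtype is the set of all cells (any type) lying within
    ``radius`` of at least one target-type cell; its alpha-shape area is the
    normalizer. Used where a cell type is too sparse for a direct alpha shape.
    """
    rows = []
    for sample, grp in cells.groupby("sample_id"):
        targets = grp[grp["cell_type"] == target_type]
        rec = {"sample_id": sample, "cell_type": target_type,
               "count": int(len(targets))}
        if targets.empty:
            rec.update(area=0.0, density=np.nan, valid=False, n_region_cells=0)
            rows.append(rec)
            continue
        tree = cKDTree(targets[["x", "y"]].to_numpy(float))
        d, _ = tree.query(grp[["x", "y"]].to_numpy(float), k=1)
        member = grp[d <= radius]
        valid = len(member) >= 3
        area = alpha_shape_area(member[["x", "y"]].to_numpy(float), alpha) if valid else 0.0
        valid = valid and area > 0
        rec.update(area=area, density=rec["count"] / area if valid else np.nan,
                   valid=valid, n_region_cells=int(len(member)))
        rows.append(rec)
    return pd.DataFrame(rows)


def region_plaque_density(
    plaques: pd.DataFrame,
    cells: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Plaque density (plaques / um^2) per annotated region per sample.

    Each plaque is assigned the region label of its nearest cell; the region
    area is the alpha shape of that region's cells. Regions with fewer than
    3 cells in a sample are excluded.
    """
    rows = []
    for sample, grp in cells.groupby("sample_id"):
        grp = grp.reset_index(drop=True)
        pl = plaques[plaques["sample_id"] == sample]
        assigned = pd.Series(dtype=object)
        if len(pl):
            idx = _nearest_cell(pl[["x", "y"]].to_numpy(float), grp)
            assigned = pd.Series(grp["region"].to_numpy(object)[idx])
        for region, reg_cells in grp.groupby("region", dropna=True):
            if len(reg_cells) < 3:
                continue
            area = alpha_shape_area(reg_cells[["x", "y"]].to_numpy(float), alpha)
            if area <= 0:
                continue
            n_pl = int((assigned == region).sum()) if len(pl) else 0
            rows.append({
                "sample_id": sample, "region": region, "n_plaques": n_pl,
                "area": area, "density": n_pl / area,
            })
    return pd.DataFrame(rows, columns=["sample_id", "region", "n_plaques", "area", "density"])


# ---------------------------------------------------------------------------
# Plaque-neuron spacing
# ---------------------------------------------------------------------------

@dataclass
class PlaqueNeuronStats:
    plaque_to_neuron: np.ndarray    # per plaque: distance to closest neuron (um)
    neuron_to_neuron: np.ndarray    # per neuron: nearest neuronal neighbor (um)
    statistic: float
    pvalue: float


def plaque_neuron_distance_stats(
    plaques: pd.DataFrame,
    cells: pd.DataFrame,
    neuron_types: set[str] | list[str],
    exclude_regions: set[str] = frozenset({"CC"}),
) -> PlaqueNeuronStats:
    """Compare plaque-to-nearest-neuron vs neuron-to-nearest-neuron distances.

    Plaques assigned (by nearest cell) to excluded regions — by default the
    corpus callosum, which lacks nearby neurons — are dropped. The two distance
    samples are compared with a two-sided Welch t-test.
    """
    neuron_types = set(neuron_types)
    if not neuron_types:
        raise ValueError("neuron_types must be non-empty")
    p2n, n2n = [], []
    for sample, grp in cells.groupby("sample_id"):
        grp = grp.reset_index(drop=True)
        neurons = grp[grp["cell_type"].isin(neuron_types)]
        pl = plaques[plaques["sample_id"] == sample]
        if len(pl) and neurons.empty:
            raise ValueError(f"sample {sample} has plaques but no neurons")
        if len(pl) and exclude_regions:
            idx = _nearest_cell(pl[["x", "y"]].to_numpy(float), grp)
            reg = grp["region"].to_numpy(object)[idx]
            pl = pl[~pd.Series(reg).isin(exclude_regions).to_numpy()]
        if len(pl):
            tree = cKDTree(neurons[["x", "y"]].to_numpy(float))
            d, _ = tree.query(pl[["x", "y"]].to_numpy(float), k=1)
            p2n.extend(np.atleast_1d(d))
        if len(neurons) >= 2:
            xy = neurons[["x", "y"]].to_numpy(float)
            tree = cKDTree(xy)
            d, _ = tree.query(xy, k=2)
            n2n.extend(d[:, 1])
    p2n = np.asarray(p2n, float)
    n2n = np.asarray(n2n, float)
    if len(p2n) < 2 or len(n2n) < 2:
        return PlaqueNeuronStats(p2n, n2n, np.nan, np.nan)
    stat, p = scipy.stats.ttest_ind(p2n, n2n, equal_var=False)
    return PlaqueNeuronStats(p2n, n2n, float(stat), float(p))


# ---------------------------------------------------------------------------
# Detection evaluation
# ---------------------------------------------------------------------------

@dataclass
class DetectionEval:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float


def evaluate_detection(predicted: pd.DataFrame, truth: pd.DataFrame,
                       match_radius: float = 15.0) -> DetectionEval:
    """Precision / recall / F1 for plaque detection by greedy centroid matching.

    Predicted and true centroids (same sample frame) are matched one-to-one in
    ascending distance order up to ``match_radius``; unmatched predictions are
    false positives, unmatched truth false negatives. Zero-denominator metrics
    are defined as 0.
    """
    pairs = []
    pred_groups = dict(tuple(predicted.groupby("sample_id"))) if len(predicted) else {}
    truth_groups = dict(tuple(truth.groupby("sample_id"))) if len(truth) else {}
    for sample in sorted(set(pred_groups) & set(truth_groups)):
        p = pred_groups[sample]
        t = truth_groups[sample]
        dx = p["x"].to_numpy(float)[:, None] - t["x"].to_numpy(float)[None, :]
        dy = p["y"].to_numpy(float)[:, None] - t["y"].to_numpy(float)[None, :]
        dist = np.hypot(dx, dy)
        pi, ti = np.nonzero(dist <= match_radius)
        for d, i, j in zip(dist[pi, ti], p.index[pi], t.index[ti]):
            pairs.append((d, i, j))
    pairs.sort(key=lambda r: (r[0], str(r[1]), str(r[2])))
    used_p, used_t = set(), set()
    for _, i, j in pairs:
        if i not in used_p and j not in used_t:
            used_p.add(i)
            used_t.add(j)
    tp = len(used_p)
    fp = len(predicted) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionEval(tp, fp, fn, precision, recall, f1)


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------

def rank_sum_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Uses the exact null distribution for small tie-free samples (n <= 8 per
    group), otherwise the normal approximation with tie correction. Degenerate
    input where every pooled value is identical returns p = 1.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
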