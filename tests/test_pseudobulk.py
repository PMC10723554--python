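import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import plaquescape as pq
from plaquescape.pseudobulk import benjamini_hochberg, lme_contrast


def bh_brute_force(p):
    """BH step-up straight from the definition, O(m^2)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_worked_example():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.04]),
                               [0.03, 0.03, 0.04])


def test_bh_trivial_cases():
    np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), [1, 1, 1])
    np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])


def test_bh_nan_excluded_from_m():
    out = benjamini_hochberg([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], bh_brute_force([0.01, 0.04]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_equals_brute_force(pvals):
    np.testing.assert_allclose(benjamini_hochberg(pvals), bh_brute_force(pvals),
                               rtol=0, atol=1e-12)


def test_bh_adjusted_never_below_raw():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=500)
    assert (benjamini_hochberg(p) >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# Pseudobulk construction
# ---------------------------------------------------------------------------

def _toy(n_per_sample, detection=None, n_genes=2):
    """Cells over samples with controllable per-gene detection."""
    rows, counts = [], []
    rng = np.random.default_rng(3)
    for s, n in n_per_sample.items():
        for i in range(n):
            rows.append({
                "cell_id": f"{s}_c{i}", "x": 0.0, "y": 0.0, "volume": 500.0,
                "cell_type": "Microglia", "subcluster": None, "region": "ctx",
                "genotype": "5xFAD" if s.startswith("f") else "WT",
                "sample_id": s, "batch_id": f"b{int(s[-1]) % 3}",
            })
            counts.append(rng.poisson(5.0, n_genes))
    cells = pd.DataFrame(rows)
    counts = np.array(counts)
    if detection is not None:
        for j, frac in enumerate(detection):
            n = len(cells)
            keep = int(round(frac * n))
            counts[:, j] = 0
            counts[:keep, j] = 1 + rng.poisson(3.0, keep)
    cm = pq.CountMatrix(sp.csr_matrix(counts),
                        [f"g{j}" for j in range(n_genes)], cells["cell_id"])
    return cells, cm


def test_detection_filter_boundary():
    cells, cm = _toy({"f1": 50, "w1": 50}, detection=[0.14, 0.15])
    pb = pq.build_pseudobulk(cells, cm, "Microglia", min_cells=1)
    assert list(pb.genes) == ["g1"]


def test_min_cells_boundary():
    cells, cm = _toy({"f1": 49, "w1": 50})
    pb = pq.build_pseudobulk(cells, cm, "Microglia")
    assert list(pb.rows["sample_id"]) == ["w1"]


def test_pseudobulk_conservation(default_run):
    _, cells, cm, _, _ = default_run
    pb = pq.build_pseudobulk(cells, cm, "Astrocyte", min_cells=1)
    mask = (cells["cell_type"] == "Astrocyte").to_numpy()
    sub = cm.subset_cells(mask)
    expected = np.asarray(sub.counts[:, sub.gene_index(pb.genes)].sum(axis=0)).ravel()
    np.testing.assert_array_equal(pb.counts.sum(axis=0), expected)


def test_pseudobulk_strata_split_rows(default_run):
    _, cells, cm, _, _ = default_run
    pb = pq.build_pseudobulk(cells, cm, "ExNeuron", strata=cells["region"], min_cells=1)
    assert {"sample_id", "stratum"} <= set(pb.rows.columns)
    assert pb.rows.groupby("sample_id")["stratum"].nunique().max() > 1


# ---------------------------------------------------------------------------
# Mixed-effect contrast
# ---------------------------------------------------------------------------

def test_identical_rows_give_zero_lfc():
    counts = np.tile([[100, 200, 300]], (8, 1))
    rows = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "genotype": ["5xFAD"] * 4 + ["WT"] * 4,
        "batch_id": ["b1", "b2"] * 4, "n_cells": 100,
    })
    pb = pq.PseudobulkMatrix(counts, np.array(["g1", "g2", "g3"], object), rows, "Microglia")
    res = lme_contrast(pb, rows["genotype"], ("5xFAD", "WT"), "t")
    assert np.allclose(res["log2fc"], 0.0)
    assert (res["pvalue"] > 0.99).all()


def test_skips_contrast_with_single_replicate():
    counts = np.random.default_rng(0).poisson(50, (3, 4))
    rows = pd.DataFrame({
        "sample_id": ["a", "b", "c"], "genotype": ["5xFAD", "WT", "WT"],
        "batch_id": "b1", "n_cells": 100,
    })
    pb = pq.PseudobulkMatrix(counts, np.array(list("wxyz"), object), rows, "Microglia")
    with pytest.warns(UserWarning, match="fewer than 2 replicates"):
        res = lme_contrast(pb, rows["genotype"], ("5xFAD", "WT"), "t")
    assert res.empty


def test_single_batch_contrast_matches_t_test():
    """With one batch the model is OLS, i.e. an equal-variance two-sample t-test."""
    rng = np.random.default_rng(4)
    counts = rng.poisson([200, 400, 100], (10, 3)) + 1
    rows = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(10)],
        "genotype": ["5xFAD"] * 5 + ["WT"] * 5,
        "batch_id": "b1", "n_cells": 100,
    })
    pb = pq.PseudobulkMatrix(counts, np.array(["g1", "g2", "g3"], object), rows, "x")
    res = lme_contrast(pb, rows["genotype"], ("5xFAD", "WT"), "t")
    y = pq.log2_cpm(counts)
    for j, gene in enumerate(["g1", "g2", "g3"]):
        t, p = scipy.stats.ttest_ind(y[:5, j], y[5:, j], equal_var=True)
        row = res[res["gene"] == gene].iloc[0]
        assert row["pvalue"] == pytest.approx(p, rel=1e-9)
        assert row["method"] == "ols"
        assert row["log2fc"] == pytest.approx(y[:5, j].mean() - y[5:, j].mean(), rel=1e-9)


def test_injected_fold_change_recovered_quickly():
    """One small recovery check: 2x shift at 8 rows/level is found."""
    rng = np.random.default_rng(5)
    base = rng.poisson(300, (16, 30)) + 1
    base[:8, 0] = rng.poisson(600, 8)       # gene 0 doubled in the first level
    rows = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(16)],
        "genotype": ["5xFAD"] * 8 + ["WT"] * 8,
        "batch_id": [f"b{i % 3}" for i in range(16)], "n_cells": 100,
    })
    genes = np.array([f"g{j}" for j in range(30)], object)
    pb = pq.PseudobulkMatrix(base, genes, rows, "x")
    res = lme_contrast(pb, rows["genotype"], ("5xFAD", "WT"), "t")
    hit = res[res["gene"] == "g0"].iloc[0]
    assert hit["significant"]
    assert hit["log2fc"] == pytest.approx(1.0, abs=0.25)


def test_pairwise_empty_subset_returns_empty(default_run):
    _, cells, cm, _, _ = default_run
    only_wt = cells[cells["genotype"] == "WT"]
    with pytest.warns(UserWarning):
        res = pq.pairwise_genotype_de(only_wt.reset_index(drop=True),
                                      cm.subset_cells((cells["genotype"] == "WT").to_numpy()),
                                      "Microglia", ("5xFAD", "Trem2R47H"))
    assert res.empty


def test_proximal_boundary_cell_is_distal():
    """A cell exactly 100 um from the plaque lands in the distal stratum."""
    rng = np.random.default_rng(6)
    rows = []
    for i in range(120):
        # 60 cells at 99.9, 60 cells exactly at 100.0
        d = 99.9 if i < 60 else 100.0
        rows.append({"cell_id": f"c{i}", "x": d, "y": 0.0, "volume": 500.0,
                     "cell_type": "Microglia", "subcluster": None, "region": "ctx",
                     "genotype": "5xFAD", "sample_id": "s1", "batch_id": "b1"})
    cells = pd.DataFrame(rows)
    cm = pq.CountMatrix(sp.csr_matrix(rng.poisson(5, (120, 3))),
                        ["g0", "g1", "g2"], cells["cell_id"])
    plaques = pd.DataFrame({"plaque_id": ["p1"], "x": [0.0], "y": [0.0],
                            "size": [900.0], "sample_id": ["s1"]})
    pb = pq.build_pseudobulk(
        cells, cm, "Microglia",
        strata=pd.Series(np.where(
            pq.nearest_plaque_distance(cells, plaques) < 100.0, "proximal", "distal"),
            index=cells.index))
    assert set(pb.rows["stratum"]) == {"proximal", "distal"}
    assert pb.rows.set_index("stratum")["n_cells"]["distal"] == 60
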