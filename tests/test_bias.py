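import numpy as np
import pandas as pd
import pytest

import plaquescape as pq
from plaquescape.datamodel import GENOTYPES


def _cells_from_counts(counts_by_subcluster, totals=None):
    """Build a cell table with given per-(subcluster, genotype) cell counts."""
    rows = []
    i = 0
    for sc, per_geno in counts_by_subcluster.items():
        for g, n in per_geno.items():
            for _ in range(n):
                rows.append({
                    "cell_id": f"c{i}", "x": 0.0, "y": 0.0, "volume": 500.0,
                    "cell_type": "Microglia", "subcluster": sc, "region": "ctx",
                    "genotype": g, "sample_id": f"{g}_s", "batch_id": "b1",
                })
                i += 1
    if totals:    # pad with filler subcluster to reach per-genotype totals
        existing = {g: sum(v.get(g, 0) for v in counts_by_subcluster.values())
                    for g in GENOTYPES}
        for g in GENOTYPES:
            for _ in range(totals.get(g, 0) - existing[g]):
                rows.append({
                    "cell_id": f"c{i}", "x": 0.0, "y": 0.0, "volume": 500.0,
                    "cell_type": "Microglia", "subcluster": "filler", "region": "ctx",
                    "genotype": g, "sample_id": f"{g}_s", "batch_id": "b1",
                })
                i += 1
    return pd.DataFrame(rows)


def test_proportions_hand_calculation():
    """Equal genotype totals: (30,30,20,20) cells -> p = (.3,.3,.2,.2)."""
    cells = _cells_from_counts(
        {"sc1": {"WT": 30, "Trem2R47H": 30, "5xFAD": 20, "Trem2R47H_5xFAD": 20}},
        totals={g: 100 for g in GENOTYPES})
    tab = pq.genotype_proportions(cells)
    row = tab.set_index("subcluster").loc["sc1"]
    np.testing.assert_allclose(
        [row["WT"], row["Trem2R47H"], row["5xFAD"], row["Trem2R47H_5xFAD"]],
        [0.3, 0.3, 0.2, 0.2])


def test_uniform_draw_is_near_quarter():
    rng = np.random.default_rng(0)
    counts = {g: int(n) for g, n in zip(GENOTYPES, rng.multinomial(4000, [0.25] * 4))}
    cells = _cells_from_counts({"sc1": counts}, totals={g: 2000 for g in GENOTYPES})
    row = pq.genotype_proportions(cells).set_index("subcluster").loc["sc1"]
    for g in GENOTYPES:
        assert row[g] == pytest.approx(0.25, abs=0.03)


def test_single_genotype_subcluster():
    cells = _cells_from_counts({"sc1": {"WT": 50}}, totals={g: 100 for g in GENOTYPES})
    row = pq.genotype_proportions(cells).set_index("subcluster").loc["sc1"]
    assert row["WT"] == 1.0


def test_normalization_cancels_genotype_total():
    """Duplicating every cell of one genotype leaves proportions unchanged."""
    cells = _cells_from_counts(
        {"sc1": {"WT": 30, "Trem2R47H": 30, "5xFAD": 20, "Trem2R47H_5xFAD": 20}},
        totals={g: 100 for g in GENOTYPES})
    doubled = pd.concat([
        cells,
        cells[cells["genotype"] == "WT"].assign(
            cell_id=lambda d: d["cell_id"] + "_dup")],
        ignore_index=True)
    t1 = pq.genotype_proportions(cells).set_index("subcluster")
    t2 = pq.genotype_proportions(doubled).set_index("subcluster")
    np.testing.assert_allclose(t1[list(GENOTYPES)].loc["sc1"],
                               t2[list(GENOTYPES)].loc["sc1"])


def test_missing_genotype_is_an_error():
    cells = _cells_from_counts({"sc1": {"WT": 10, "5xFAD": 10}})
    with pytest.raises(ValueError, match="zero cells"):
        pq.genotype_proportions(cells)


def _bias_row(p, size_fraction=0.5, subcluster="sc"):
    return pd.DataFrame([{
        "subcluster": subcluster, **dict(zip(GENOTYPES, p)),
        "n_cells": 100, "size_fraction": size_fraction,
    }])


@pytest.mark.parametrize("p, expected", [
    ((0.25, 0.25, 0.25, 0.25), "unbiased"),
    ((0.35, 0.25, 0.20, 0.20), "enriched:WT"),
    ((0.31, 0.31, 0.19, 0.19), "enriched:WT+Trem2R47H"),
    ((0.30, 0.30, 0.20, 0.20), "unbiased"),       # pair sums to exactly 0.60
    ((0.20, 0.20, 0.31, 0.29), "unbiased"),       # nothing crosses a threshold
    ((0.20, 0.19, 0.31, 0.30), "enriched:5xFAD+Trem2R47H_5xFAD"),
])
def test_classification_worked_examples(p, expected):
    out = pq.classify_bias(_bias_row(p))
    assert out.loc[0, "classification"] == expected
    assert not out.loc[0, "excluded"]


def test_diagonal_pairs_never_reported():
    # WT + double mutant sum to 0.70 but share no genetic factor
    out = pq.classify_bias(_bias_row((0.33, 0.15, 0.17, 0.33)))
    assert out.loc[0, "classification"] == "unbiased"


def test_single_label_shadows_pair_label():
    out = pq.classify_bias(_bias_row((0.40, 0.30, 0.15, 0.15)))
    assert out.loc[0, "classification"] == "enriched:WT"


def test_small_subclusters_excluded_before_classification():
    out = pq.classify_bias(_bias_row((0.90, 0.05, 0.03, 0.02), size_fraction=0.04))
    assert out.loc[0, "excluded"]
    assert out.loc[0, "classification"] is None


def test_classification_invariant_to_balanced_duplication():
    cells = _cells_from_counts(
        {"sc1": {"WT": 35, "Trem2R47H": 25, "5xFAD": 20, "Trem2R47H_5xFAD": 20}},
        totals={g: 100 for g in GENOTYPES})
    dup = pd.concat([cells, cells.assign(cell_id=lambda d: d["cell_id"] + "_dup")],
                    ignore_index=True)
    c1 = pq.classify_bias(pq.genotype_proportions(cells)).set_index("subcluster")
    c2 = pq.classify_bias(pq.genotype_proportions(dup)).set_index("subcluster")
    assert c1.loc["sc1", "classification"] == c2.loc["sc1", "classification"] == "enriched:WT"


def test_state_proportions_all_homeostatic():
    cells = _cells_from_counts({"sc1": {g: 25 for g in GENOTYPES}})
    states = pd.Series("homeostatic", index=cells.index)
    per, _ = pq.state_region_proportions(cells, states, "DAM")
    assert (per["proportion"] == 0.0).all()


def test_dam_proportion_tracks_plaque_density(default_run):
    """Regions with more plaques have higher DAM fractions (rank agreement)."""
    _, cells, _, plaques, truth = default_run
    micro = cells[cells["cell_type"] == "Microglia"]
    states = truth.cell_truth.set_index("cell_id")["state"]
    st = pd.Series(states.loc[micro["cell_id"]].to_numpy(), index=micro.index)
    amyloid = micro["genotype"].isin(pq.AMYLOID_GENOTYPES)
    per, _ = pq.state_region_proportions(micro[amyloid], st[amyloid], "DAM")
    dam_by_region = per.groupby("region")["proportion"].mean()
    pl_density = pq.region_plaque_density(plaques, cells).groupby("region")["density"].mean()
    common = dam_by_region.index.intersection(pl_density.index)
    rho = pd.Series(dam_by_region[common]).corr(pd.Series(pl_density[common]), method="spearman")
    assert rho > 0.5
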