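import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

import plaquescape as pq


def _cells(xy, cell_type="Microglia", sample="s1", ids=None, region=None):
    n = len(xy)
    return pd.DataFrame({
        "cell_id": ids if ids is not None else [f"c{i:04d}" for i in range(n)],
        "x": [p[0] for p in xy], "y": [p[1] for p in xy],
        "volume": 500.0,
        "cell_type": cell_type if isinstance(cell_type, list) else [cell_type] * n,
        "subcluster": None,
        "region": region if isinstance(region, list) else [region] * n,
        "genotype": "5xFAD", "sample_id": sample, "batch_id": "b1",
    })


def _plaques(xy, sample="s1"):
    return pd.DataFrame({
        "plaque_id": [f"p{i:04d}" for i in range(len(xy))],
        "x": [p[0] for p in xy], "y": [p[1] for p in xy],
        "size": 900.0, "sample_id": sample,
    })


# ---------------------------------------------------------------------------
# Nearest distances
# ---------------------------------------------------------------------------

def test_nearest_plaque_distance_3_4_5():
    cells = _cells([(0, 0)])
    plaques = _plaques([(3, 4), (10, 0)])
    assert pq.nearest_plaque_distance(cells, plaques).iloc[0] == pytest.approx(5.0)


def test_no_plaques_gives_infinite_sentinel():
    d = pq.nearest_plaque_distance(_cells([(0, 0), (1, 1)]), _plaques([]))
    assert np.isinf(d).all()


def test_plaques_from_unknown_sample_rejected():
    with pytest.raises(ValueError, match="absent"):
        pq.nearest_plaque_distance(_cells([(0, 0)]), _plaques([(1, 1)], sample="ghost"))


def test_nearest_distance_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(5):
        n, m = rng.integers(5, 300), rng.integers(2, 50)
        cxy = rng.uniform(0, 800, (n, 2))
        pxy = rng.uniform(0, 800, (m, 2))
        d = pq.nearest_plaque_distance(_cells(cxy.tolist()), _plaques(pxy.tolist()))
        oracle = np.array([min(np.hypot(x - px, y - py) for px, py in pxy)
                           for x, y in cxy])
        np.testing.assert_allclose(d.to_numpy(), oracle, rtol=0, atol=1e-9)


def test_closest_cell_type_examples():
    cells = _cells([(0, 0), (5, 0)], cell_type=["Microglia", "Microglia"])
    props = pq.closest_cell_type_proportions(_plaques([(1, 0), (4, 0)]), cells)
    assert props["proportion"].tolist() == [1.0]

    cells = _cells([(0, 0), (10, 0)], cell_type=["Microglia", "Astrocyte"])
    props = pq.closest_cell_type_proportions(_plaques([(1, 0), (9, 0)]), cells)
    assert sorted(props["proportion"]) == [0.5, 0.5]


def test_closest_cell_matches_oracle_and_sums_to_one():
    rng = np.random.default_rng(1)
    cxy = rng.uniform(0, 500, (120, 2))
    pxy = rng.uniform(0, 500, (40, 2))
    types = list(rng.choice(["Microglia", "Astrocyte", "ExNeuron"], 120))
    cells = _cells(cxy.tolist(), cell_type=types)
    props = pq.closest_cell_type_proportions(_plaques(pxy.tolist()), cells)
    assert props["proportion"].sum() == pytest.approx(1.0)
    oracle = {}
    for px, py in pxy:
        j = int(np.argmin(np.hypot(cxy[:, 0] - px, cxy[:, 1] - py)))
        oracle[types[j]] = oracle.get(types[j], 0) + 1
    for _, row in props.iterrows():
        assert row["n_plaques"] == oracle[row["cell_type"]]


def test_closest_cell_tie_broken_by_smallest_id():
    cells = _cells([(0, 1), (0, -1)], cell_type=["Astrocyte", "Microglia"],
                   ids=["c_b", "c_a"])
    props = pq.closest_cell_type_proportions(_plaques([(0, 0)]), cells)
    assert props["cell_type"].tolist() == ["Microglia"]   # c_a < c_b


# ---------------------------------------------------------------------------
# Alpha shapes
# ---------------------------------------------------------------------------

def test_alpha_shape_triangle_circumradius_cases():
    # right triangle with legs 100: circumradius 70.7 um > 1/0.015 = 66.7 -> rejected
    assert pq.alpha_shape_area(np.array([(0, 0), (100, 0), (0, 100)])) == 0.0
    # legs 60: circumradius 42.4 um < 66.7 -> kept, area = 1800
    assert pq.alpha_shape_area(np.array([(0, 0), (60, 0), (0, 60)])) == pytest.approx(1800.0)


def test_alpha_shape_dense_grid_area():
    pts = np.array([(x, y) for x in range(0, 101, 5) for y in range(0, 101, 5)], float)
    assert pq.alpha_shape_area(pts) == pytest.approx(10_000.0, rel=0.05)


def test_alpha_zero_recovers_convex_hull():
    rng = np.random.default_rng(2)
    for _ in range(20):
        pts = rng.uniform(0, 300, (rng.integers(5, 60), 2))
        hull = ConvexHull(pts).volume
        assert pq.alpha_shape_area(pts, alpha=0.0) == pytest.approx(hull, rel=1e-9)


def test_alpha_shape_invariances():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 200, (80, 2))
    base = pq.alpha_shape_area(pts)
    shifted = pq.alpha_shape_area(pts + [1234.5, -987.0])
    theta = 0.7
    rot = pts @ np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rotated = pq.alpha_shape_area(rot)
    assert shifted == pytest.approx(base, rel=1e-9)
    assert rotated == pytest.approx(base, rel=1e-6)
    assert base <= ConvexHull(pts).volume + 1e-9


def test_alpha_shape_degenerate_inputs():
    assert pq.alpha_shape_area(np.array([(0, 0), (1, 1)])) == 0.0
    assert pq.alpha_shape_area(np.array([(0, 0), (1, 1), (2, 2), (3, 3)])) == 0.0
    dup = np.array([(0, 0), (0, 0), (60, 0), (0, 60)])
    assert pq.alpha_shape_area(dup) == pytest.approx(1800.0)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def test_no_target_cells_in_band_gives_zero_density():
    rng = np.random.default_rng(4)
    xy = rng.uniform(0, 80, (30, 2)).tolist()
    cells = _cells(xy, cell_type="Astrocyte")
    rep = pq.proximal_distal_density(cells, _plaques([(40, 40)]), "Microglia")
    assert rep.loc[0, "proximal_count"] == 0
    assert rep.loc[0, "proximal_density"] == 0.0


def test_proximal_plus_distal_counts_conserved(default_run):
    _, cells, _, plaques, _ = default_run
    rep = pq.proximal_distal_density(cells, plaques, "Microglia")
    d = pq.nearest_plaque_distance(cells, plaques)
    for _, row in rep.iterrows():
        in_sample = cells["sample_id"] == row["sample_id"]
        micro = in_sample & (cells["cell_type"] == "Microglia")
        within = int(((d < 500.0) & micro).sum())
        assert row["proximal_count"] + row["distal_count"] == within


def test_density_scaling_law():
    rng = np.random.default_rng(5)
    xy = rng.uniform(0, 300, (200, 2))
    types = ["Microglia" if i % 4 == 0 else "ExNeuron" for i in range(200)]
    cells = _cells(xy.tolist(), cell_type=types)
    plaques = _plaques(rng.uniform(0, 300, (5, 2)).tolist())
    rep1 = pq.proximal_distal_density(cells, plaques, "Microglia")
    cells2 = cells.assign(x=cells["x"] * 2, y=cells["y"] * 2)
    plaques2 = plaques.assign(x=plaques["x"] * 2, y=plaques["y"] * 2)
    rep2 = pq.proximal_distal_density(cells2, plaques2, "Microglia",
                                      proximal_radius=200.0, distal_band=(200.0, 1000.0),
                                      alpha=0.015 / 2)
    for col in ("proximal", "distal"):
        if rep1.loc[0, f"{col}_valid"]:
            assert rep2.loc[0, f"{col}_density"] == pytest.approx(
                rep1.loc[0, f"{col}_density"] / 4.0, rel=1e-9)


def test_subtype_region_density_constructed():
    # a single target cell with a tight 60-um triangle of neighbors
    xy = [(0, 0), (60, 0), (0, 60), (30, 20), (500, 500)]
    types = ["ExNeuron", "ExNeuron", "ExNeuron", "Microglia", "ExNeuron"]
    rep = pq.subtype_region_density(_cells(xy, cell_type=types), "Microglia")
    expected_area = pq.alpha_shape_area(np.array(xy[:4], float))
    assert rep.loc[0, "valid"]
    assert rep.loc[0, "area"] == pytest.approx(expected_area)
    assert rep.loc[0, "density"] == pytest.approx(1.0 / expected_area)


def test_subtype_region_density_flags_isolated_target():
    xy = [(0, 0), (500, 500), (900, 100)]
    types = ["Microglia", "ExNeuron", "ExNeuron"]
    rep = pq.subtype_region_density(_cells(xy, cell_type=types), "Microglia")
    assert not rep.loc[0, "valid"]
    assert np.isnan(rep.loc[0, "density"])


def test_subtype_region_membership_matches_brute_force():
    rng = np.random.default_rng(6)
    xy = rng.uniform(0, 400, (150, 2))
    types = list(rng.choice(["Microglia", "ExNeuron"], 150, p=[0.2, 0.8]))
    cells = _cells(xy.tolist(), cell_type=types)
    rep = pq.subtype_region_density(cells, "Microglia")
    targets = xy[[t == "Microglia" for t in types]]
    member = [
        any(np.hypot(x - tx, y - ty) <= 50.0 for tx, ty in targets)
        for x, y in xy
    ]
    assert rep.loc[0, "n_region_cells"] == sum(member)


def test_region_plaque_density():
    rng = np.random.default_rng(7)
    xy = rng.uniform(0, 100, (40, 2)).tolist()
    cells = _cells(xy, region="ctx")
    # no plaques -> zero density everywhere
    rep = pq.region_plaque_density(_plaques([]), cells)
    assert (rep["density"] == 0).all()
    # constructed: area from the same alpha shape, two plaques inside
    rep = pq.region_plaque_density(_plaques([(50, 50), (20, 20)]), cells)
    area = pq.alpha_shape_area(np.array(xy))
    assert rep.loc[0, "density"] == pytest.approx(2.0 / area)


def test_plaque_region_tie_assignment_deterministic():
    cells = _cells([(0, 1), (0, -1)], region=["north", "south"], ids=["c_b", "c_a"])
    rep = pq.region_plaque_density(_plaques([(0, 0)]),
                                   pd.concat([cells, _cells([(1, 1), (2, -1), (-3, -1),
                                                             (1, -2), (3, 1), (-2, 2)],
                                                            region=["north", "south", "south",
                                                                    "south", "north", "north"],
                                                            ids=[f"d{i}" for i in range(6)])],
                                             ignore_index=True))
    south = rep[rep["region"] == "south"]
    assert south["n_plaques"].iloc[0] == 1     # c_a (south) wins the tie


# ---------------------------------------------------------------------------
# Plaque-neuron spacing
# ---------------------------------------------------------------------------

def test_neuron_nearest_neighbor_matches_oracle():
    rng = np.random.default_rng(8)
    xy = rng.uniform(0, 300, (60, 2))
    cells = _cells(xy.tolist(), cell_type="ExNeuron")
    stats = pq.plaque_neuron_distance_stats(_plaques([(10, 10), (200, 200)]),
                                            cells, {"ExNeuron"}, exclude_regions=set())
    oracle = [min(np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
                  for j in range(60) if j != i) for i in range(60)]
    np.testing.assert_allclose(np.sort(stats.neuron_to_neuron), np.sort(oracle), atol=1e-9)


def test_neuron_free_sample_with_plaques_errors():
    cells = _cells([(0, 0), (5, 5)], cell_type="Microglia")
    with pytest.raises(ValueError, match="no neurons"):
        pq.plaque_neuron_distance_stats(_plaques([(1, 1)]), cells, {"ExNeuron"})


def test_identical_distance_distributions_not_significant():
    """Null calibration: plaques placed like neurons give unremarkable p."""
    rng = np.random.default_rng(9)
    pvals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 1000, (150, 2))
        cells = _cells(xy.tolist(), cell_type="ExNeuron")
        pl = _plaques(rng.uniform(0, 1000, (150, 2)).tolist())
        stats = pq.plaque_neuron_distance_stats(pl, cells, {"ExNeuron"},
                                                exclude_regions=set())
        pvals.append(stats.pvalue)
    assert np.median(pvals) > 0.05


# ---------------------------------------------------------------------------
# Detection evaluation
# ---------------------------------------------------------------------------

def test_perfect_detection():
    truth = _plaques([(0, 0), (50, 50), (90, 10)])
    ev = pq.evaluate_detection(truth, truth, match_radius=15.0)
    assert (ev.precision, ev.recall, ev.f1) == (1.0, 1.0, 1.0)


def test_detection_f1_worked_example():
    """23 matches, 1 spurious detection, 5 misses -> F1 ~ 0.885."""
    rng = np.random.default_rng(10)
    txy = rng.uniform(0, 2000, (28, 2))
    truth = _plaques(txy.tolist())
    pred_xy = np.vstack([txy[:23] + [1.0, 0.5], [[9999.0, 9999.0]]])
    pred = _plaques(pred_xy.tolist())
    ev = pq.evaluate_detection(pred, truth, match_radius=15.0)
    assert (ev.true_positives, ev.false_positives, ev.false_negatives) == (23, 1, 5)
    assert ev.precision == pytest.approx(23 / 24)
    assert ev.recall == pytest.approx(23 / 28)
    assert ev.f1 == pytest.approx(2 * (23 / 24) * (23 / 28) / (23 / 24 + 23 / 28))


def test_empty_prediction():
    ev = pq.evaluate_detection(_plaques([]), _plaques([(0, 0), (10, 10)]), 15.0)
    assert ev.recall == 0.0 and ev.f1 == 0.0 and ev.false_negatives == 2


def test_detection_count_conservation():
    rng = np.random.default_rng(11)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        truth = _plaques(rng.uniform(0, 500, (rng.integers(3, 30), 2)).tolist())
        pred = _plaques(rng.uniform(0, 500, (rng.integers(3, 30), 2)).tolist())
        ev = pq.evaluate_detection(pred, truth, match_radius=40.0)
        assert ev.true_positives + ev.false_negatives == len(truth)
        assert ev.true_positives + ev.false_positives == len(pred)


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------

def test_rank_sum_exact_enumeration():
    _, p = pq.rank_sum_compare([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_rank_sum_self_comparison_is_null():
    _, p = pq.rank_sum_compare([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_rank_sum_degenerate_identical_values():
    stat, p = pq.rank_sum_compare([5, 5, 5], [5, 5])
    assert p == 1.0


def test_rank_sum_normal_approximation_close_to_exact_at_n8():
    rng = np.random.default_rng(12)
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.8, 1, 8)
    _, p_exact = pq.rank_sum_compare(list(a), list(b))
    import scipy.stats
    p_approx = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue
    assert abs(p_exact - p_approx) < 0.01


def test_rank_sum_requires_two_per_group():
    with pytest.raises(ValueError):
        pq.rank_sum_compare([1.0], [2.0, 3.0])
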