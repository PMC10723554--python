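import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import plaquescape as pq


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        yield


@pytest.fixture
def tiny_dataset():
    """Three cells, two genes, one plaque — a hand-checkable fixture."""
    cells = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3"],
        "x": [0.0, 3.0, 10.0],
        "y": [0.0, 4.0, 0.0],
        "volume": [500.0, 700.0, 900.0],
        "cell_type": ["Microglia", "Astrocyte", "Microglia"],
        "subcluster": [None, None, None],
        "region": ["neocortex", "neocortex", "CC"],
        "genotype": ["5xFAD", "5xFAD", "5xFAD"],
        "sample_id": ["s1", "s1", "s1"],
        "batch_id": ["b1", "b1", "b1"],
    })
    cm = pq.CountMatrix(
        sp.csr_matrix(np.array([[5, 0], [2, 3], [0, 7]])),
        gene_names=["Hexb", "Gfap"],
        cell_ids=["c1", "c2", "c3"],
    )
    plaques = pd.DataFrame({
        "plaque_id": ["p1"], "x": [0.0], "y": [0.0], "size": [900.0],
        "sample_id": ["s1"],
    })
    return cells, cm, plaques


@pytest.fixture(scope="session")
def default_run():
    """One study-like simulated dataset shared by read-only tests."""
    cfg = pq.default_config(seed=11)
    cells, cm, plaques, truth = pq.simulate_dataset(cfg)
    return cfg, cells, cm, plaques, truth


def small_null_config(seed, n_genes=120, genotypes=("WT", "5xFAD"),
                      n_per_genotype=4, density=3.0e-4, side=1000.0,
                      with_plaques=False, **overrides):
    """A compact single-cell-type configuration with no injected effects."""
    samples = []
    for i in range(n_per_genotype):
        for g in genotypes:
            samples.append(pq.SampleSpec(f"{g}_{i + 1}", g, f"B{i % 3 + 1}"))
    regions = [pq.RegionSpec("ctx", 0, 0, side, side)]
    plaque = pq.PlaqueConfig(intensity={"ctx": 4.0e-5}) if with_plaques else None
    return pq.SimulationConfig(
        seed=seed,
        samples=samples,
        regions=regions,
        cell_types=["Microglia"],
        densities={"Microglia": {"ctx": density}},
        n_genes=n_genes,
        plaque=plaque,
        **overrides,
    )
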