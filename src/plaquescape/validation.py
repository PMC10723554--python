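"""Self-validation experiments: calibration and ground-truth recovery.

Each function builds a purpose-specific synthetic configuration, runs the
relevant pipeline stage, and summarizes how well the method recovers what the
generator injected (or how calibrated it is when nothing was injected). They
back both the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes follow the validation design: pseudobulk contrasts are checked
with 8 replicates per level in 3 imaging batches, the null calibration with a
2,000-gene panel over 4 samples per genotype, and the distance regression
with roughly 500 cells inside the 100 um fitting window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .distance_de import continuous_distance_de
from .filters import filter_neuronal_de
from .pseudobulk import pairwise_genotype_de, proximal_distal_de, regional_de
from .simulate import (
    Effect,
    PlaqueConfig,
    RegionSpec,
    SampleSpec,
    SimulationConfig,
    StateConfig,
    derive_annotation,
    simulate_dataset,
)


def _samples(genotypes, n_per_genotype, n_batches=3):
    out = []
    for i in range(n_per_genotype):
        for g in genotypes:
            out.append(SampleSpec(f"{g}_{i + 1}", g, f"B{i % n_batches + 1}"))
    return out


def _base_config(seed, genotypes=("5xFAD", "WT"), n_per_genotype=4, n_genes=300,
                 density=3.0e-4, side=1000.0, with_plaques=False, **overrides):
    plaque = PlaqueConfig(intensity={"ctx": 4.0e-5}) if with_plaques else None
    return SimulationConfig(
        seed=seed,
        samples=_samples(genotypes, n_per_genotype),
        regions=[RegionSpec("ctx", 0, 0, side, side)],
        cell_types=["Microglia"],
        densities={"Microglia": {"ctx": density}},
        n_genes=n_genes,
        plaque=plaque,
        **overrides,
    )


def _run_pairwise(cfg, pair=("5xFAD", "WT"), cell_type="Microglia"):
    cells, cm, _, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pairwise_genotype_de(cells, cm, cell_type, pair)


# ---------------------------------------------------------------------------
# Mixed-model calibration
# ---------------------------------------------------------------------------

def null_pairwise_calibration(seed: int, n_genes: int = 2000) -> dict:
    """Type-I behaviour of pairwise pseudobulk DE on a null dataset.

    4 samples per genotype over 3 batches, no injected effects: the fraction
    of analyzed genes with raw p < 0.05 should sit near the nominal level.
    """
    res = _run_pairwise(_base_config(seed, n_genes=n_genes))
    return {
        "frac_p_lt_05": float((res["pvalue"] < 0.05).mean()),
        "n_genes": int(len(res)),
    }


def pairwise_fdr_experiment(seed: int, n_seeds: int = 20, n_genes: int = 300,
                            n_effects: int = 30) -> dict:
    """Realized false-discovery proportion at BH 0.05, averaged over seeds.

    Each replicate injects ``n_effects`` genotype effects of |log2FC| = 1 into
    an otherwise null panel. FDP is measured among the pipeline's discovery
    set (|log2FC| >= 0.35 and BH padj < 0.05); the FDP of a padj-only rule is
    reported alongside for reference.
    """
    fdps, fdps_padj_only = [], []
    for k in range(n_seeds):
        injected = [f"G{j:03d}" for j in range(n_effects)]
        effects = [Effect(g, "Microglia", "genotype", 1.0 if j % 2 else -1.0,
                          ("5xFAD",))
                   for j, g in enumerate(injected)]
        cfg = _base_config(seed + 1000 * k, n_genes=n_genes, effects=effects)
        res = _run_pairwise(cfg)
        for calls, store in ((res[res["significant"]], fdps),
                             (res[res["padj"] < 0.05], fdps_padj_only)):
            store.append(float((~calls["gene"].isin(injected)).mean())
                         if len(calls) else 0.0)
    return {"mean_fdp": float(np.mean(fdps)),
            "mean_fdp_padj_only": float(np.mean(fdps_padj_only)),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Effect recovery, three pseudobulk families
# ---------------------------------------------------------------------------

def _score(res: pd.DataFrame, truth: dict[str, float]) -> dict:
    found = res.set_index("gene")
    detected, errors = [], []
    for gene, lfc in truth.items():
        if gene in found.index:
            detected.append(bool(found.loc[gene, "significant"]))
            errors.append(float(found.loc[gene, "log2fc"]) - lfc)
        else:
            detected.append(False)
    return {
        "sensitivity": float(np.mean(detected)),
        "mae": float(np.mean(np.abs(errors))) if errors else float("nan"),
        "n_effects": len(truth),
    }


def pairwise_recovery(seed: int, n_injected: int = 20) -> dict:
    """Recovery of |log2FC| = 1 genotype effects at 8 pseudobulk rows/level."""
    truth = {f"G{j:03d}": (1.0 if j % 2 else -1.0) for j in range(n_injected)}
    effects = [Effect(g, "Microglia", "genotype", lfc, ("5xFAD",))
               for g, lfc in truth.items()]
    cfg = _base_config(seed, n_per_genotype=8, effects=effects)
    return _score(_run_pairwise(cfg), truth)


def regional_recovery(seed: int, n_injected: int = 20) -> dict:
    """Recovery of region-vs-rest effects (target region in 8 samples)."""
    truth = {f"G{j:03d}": 1.0 for j in range(n_injected)}
    effects = [Effect(g, "Microglia", "region", lfc, ("r1",))
               for g, lfc in truth.items()]
    regions = [RegionSpec(f"r{i}", 1100 * i, 0, 1100 * i + 1000, 1000) for i in range(4)]
    cfg = SimulationConfig(
        seed=seed,
        samples=_samples(("WT",), 8),
        regions=regions,
        cell_types=["Microglia"],
        densities={"Microglia": {r.name: 1.0e-4 for r in regions}},
        n_genes=300,
        effects=effects,
    )
    cells, cm, _, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = regional_de(cells, cm, "Microglia", "r1")
    return _score(res, truth)


def proximity_recovery(seed: int, n_injected: int = 20) -> dict:
    """Recovery of plaque-proximal upregulation (proximal vs distal strata)."""
    truth = {f"G{j:03d}": 1.0 for j in range(n_injected)}
    effects = [Effect(g, "Microglia", "proximal", lfc) for g, lfc in truth.items()]
    cfg = _base_config(seed, genotypes=("5xFAD",), n_per_genotype=8,
                       density=4.0e-4, with_plaques=True, effects=effects)
    cells, cm, plaques, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proximal_distal_de(cells, cm, plaques, "Microglia")
    return _score(res, truth)


# ---------------------------------------------------------------------------
# Distance regression
# ---------------------------------------------------------------------------

def distance_slope_recovery(seed: int, n_seeds: int = 20,
                            true_slope: float = -1.0) -> dict:
    """Slope recovery at ~500 window cells, repeated over seeds.

    The target gene is a well-expressed panel gene (baseline mean 4); each
    seed draws a fresh single plaque-bearing sample.
    """
    estimates = []
    for k in range(n_seeds):
        cfg = _base_config(seed + 1000 * k, genotypes=("5xFAD",), n_per_genotype=1,
                           n_genes=300, density=1.2e-3, side=800.0,
                           with_plaques=True,
                           markers={"Microglia": {"Tgt": 4.0}},
                           effects=[Effect("Tgt", "Microglia", "distance", true_slope)])
        cells, cm, plaques, _ = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = continuous_distance_de(cells, cm, plaques, "Microglia",
                                         genes=["Tgt"])
        estimates.append(float(res.set_index("gene").loc["Tgt", "log2fc"]))
    estimates = np.asarray(estimates)
    return {
        "mean_estimate": float(estimates.mean()),
        "mean_abs_error": float(np.abs(estimates - true_slope).mean()),
        "sign_agreement": float((np.sign(estimates) == np.sign(true_slope)).mean()),
        "n_seeds": n_seeds,
    }


def distance_null_calibration(seed: int, n_genes: int = 1000) -> dict:
    """Raw p < 0.05 fraction for the distance slope on null, well-expressed genes."""
    cfg = _base_config(seed, genotypes=("5xFAD",), n_per_genotype=1,
                       n_genes=n_genes, density=1.2e-3, side=800.0,
                       with_plaques=True,
                       baseline_log_mean=float(np.log(2.0)), baseline_log_sd=0.5)
    cells, cm, plaques, _ = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = continuous_distance_de(cells, cm, plaques, "Microglia")
    return {
        "frac_p_lt_05": float((res["pvalue"] < 0.05).mean()),
        "n_genes": int(len(res)),
    }


# ---------------------------------------------------------------------------
# Spillover filtering
# ---------------------------------------------------------------------------

SPILL_MARKERS = {
    # strongly expressed glial genes, the ones whose spillover is visible;
    # Gfap/Apoe sit among the highest-expressed genes of a typical panel
    "Microglia": {"Hexb": 7.0, "Cx3cr1": 5.0, "Tmem119": 4.0, "P2ry12": 4.0,
                  "Apoe": 4.0, "Itgax": 0.5, "Cst7": 0.5},
    "Astrocyte": {"Slc1a3": 7.0, "Aqp4": 5.0, "Gfap": 5.0, "Clu": 4.0, "C4b": 2.0},
    "ExNeuron": {"Slc17a7": 8.0, "Satb2": 5.0},
}
SPILL_STATES = [
    StateConfig("Microglia", "DAM", 0.9, 60.0,
                {"Itgax": 3.5, "Cst7": 3.5, "Apoe": 2.0, "P2ry12": -1.5, "Tmem119": -1.0}),
    StateConfig("Astrocyte", "DAA", 0.7, 60.0,
                {"Gfap": 2.5, "C4b": 3.0, "Clu": 1.5}),
]


def _spillover_config(seed: int, rate: float, n_injected: int) -> SimulationConfig:
    effects = [Effect(f"G{j:03d}", "ExNeuron", "genotype", 1.0 if j % 2 else -1.0,
                      ("5xFAD",)) for j in range(n_injected)]
    densities = {"Microglia": 1.2e-4, "Astrocyte": 1.2e-4, "ExNeuron": 3.5e-4}
    return SimulationConfig(
        seed=seed,
        samples=_samples(("5xFAD", "WT"), 4),
        regions=[RegionSpec("ctx", 0, 0, 1200, 1200)],
        cell_types=list(densities),
        densities={ct: {"ctx": d} for ct, d in densities.items()},
        n_genes=300,
        markers={k: dict(v) for k, v in SPILL_MARKERS.items()},
        states=[StateConfig(s.cell_type, s.state_name, s.max_prob, s.decay_um,
                            dict(s.signature)) for s in SPILL_STATES],
        plaque=PlaqueConfig(intensity={"ctx": 4.0e-5}),
        effects=effects,
        spillover_rate=rate,
    )


def spillover_filter_experiment(seed: int, rate: float = 0.1,
                                n_injected: int = 20) -> dict:
    """Neuronal DE with segmentation spillover, before and after filtering.

    Runs the same design with and without spillover. Reports how many glial /
    DAM / DAA marker genes are falsely called DE in excitatory neurons before
    filtering, the fraction of those removed by the neuronal filter, and the
    ratio of sensitivity to the injected neuronal effects (spillover run vs
    clean run).
    """
    truth = {f"G{j:03d}": (1.0 if j % 2 else -1.0) for j in range(n_injected)}
    results = {}
    for label, r in (("spill", rate), ("clean", 0.0)):
        cfg = _spillover_config(seed, r, n_injected)
        cells, cm, _, _ = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_genotype_de(cells, cm, "ExNeuron", ("5xFAD", "WT"))
        results[label] = (res, derive_annotation(cfg))
    res_spill, annotation = results["spill"]
    marker_set = set(annotation.glial_markers) | set(annotation.dam_markers) \
        | set(annotation.daa_markers)
    false_markers = res_spill[res_spill["significant"]
                              & res_spill["gene"].isin(marker_set)]["gene"].tolist()
    kept, _ = filter_neuronal_de(res_spill, annotation)
    remaining = kept[kept["significant"] & kept["gene"].isin(marker_set)]
    removal = 1.0 if not false_markers else \
        1.0 - len(remaining) / len(false_markers)
    sens_spill = _score(res_spill, truth)["sensitivity"]
    sens_clean = _score(results["clean"][0], truth)["sensitivity"]
    return {
        "n_false_marker_calls_prefilter": int(len(false_markers)),
        "marker_removal_fraction": float(removal),
        "sensitivity_with_spillover": float(sens_spill),
        "sensitivity_clean": float(sens_clean),
        "sensitivity_ratio": float(sens_spill / sens_clean) if sens_clean else float("nan"),
    }
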