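"""Synthetic MERFISH-like datasets with known ground truth.

The generator emulates the statistical structure of an imaging-based spatial
transcriptomics study of amyloid pathology: four genotypes (WT, Trem2R47H,
5xFAD, Trem2R47H;5xFAD) across multiple samples and imaging batches; named
rectangular tissue regions; cells placed by independent spatial Poisson
processes per region and cell type; plaques by a spatial Poisson process whose
intensity is nonzero only in 5xFAD-carrying genotypes; negative-binomial
counts over a ~300-gene panel with log-normal library-size variation and
batch effects; distance-dependent disease-associated microglia / astrocyte
(DAM / DAA) activation; genotype-biased subclusters; and optional
segmentation-spillover contamination between spatial neighbors.

Every injected effect is recorded in a :class:`TruthLog` so downstream
analyses can be scored for recovery. One RNG stream is derived per sample
from the master seed and the sample id, so adding samples never perturbs
existing ones; a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .datamodel import AMYLOID_GENOTYPES, GENOTYPES, CountMatrix, ExpressionAnnotation

GLIAL_TYPES = ("Microglia", "Astrocyte", "Oligodendrocyte")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SampleSpec:
    sample_id: str
    genotype: str
    batch_id: str


@dataclass
class RegionSpec:
    """Axis-aligned rectangular region in the sample frame (um)."""
    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def overlaps(self, other: "RegionSpec") -> bool:
        return (self.x0 < other.x1 and other.x0 < self.x1
                and self.y0 < other.y1 and other.y0 < self.y1)


@dataclass
class Effect:
    """One injected expression effect.

    kind:
      * ``genotype``: multiply the gene's mean by 2**effect in every listed
        genotype (``target`` = tuple of genotypes);
      * ``region``: 2**effect for cells in the named region;
      * ``proximal``: 2**effect for cells within 100 um of a plaque;
      * ``distance``: a linear log2 trend, ``effect`` per 100 um of distance
        to the nearest plaque, applied inside the 100 um window and zero
        beyond it.
    """
    gene: str
    cell_type: str
    kind: str
    effect: float
    target: tuple = ()

    def contrast(self) -> str:
        if self.kind == "genotype":
            return f"genotype:{'+'.join(self.target)}"
        if self.kind == "region":
            return f"region:{self.target[0]}"
        if self.kind == "proximal":
            return "proximal"
        return "distance-slope"


@dataclass
class StateConfig:
    """Distance-decaying disease-state assignment for one glial type."""
    cell_type: str
    state_name: str                     # e.g. "DAM", "DAA"
    max_prob: float                     # activation probability at distance 0
    decay_um: float                     # exponential decay length of p(state)
    signature: dict = field(default_factory=dict)   # gene -> log2 shift in state


@dataclass
class SubclusterSpec:
    name: str
    genotype_weights: dict              # genotype -> relative weight


@dataclass
class PlaqueConfig:
    intensity: dict                     # region -> plaques / um^2 (amyloid genotypes)
    genotype_factors: dict = field(default_factory=lambda: {
        "WT": 0.0, "Trem2R47H": 0.0, "5xFAD": 1.0, "Trem2R47H_5xFAD": 0.8,
    })
    size_log_mean: float = np.log(900.0)    # um^3; gives mean ~ 1,000 um^3
    size_log_sd: float = 0.5


@dataclass
class SimulationConfig:
    seed: int
    samples: list
    regions: list
    cell_types: list
    densities: dict                     # cell_type -> {region -> cells/um^2}
    n_genes: int = 300
    baseline_log_mean: float = np.log(0.5)
    baseline_log_sd: float = 1.0
    baseline_floor: float = 0.05        # counts/cell; keeps every background
                                        # gene annotated as expressed
    marker_off_mean: float = 0.02       # marker expression outside its own type
    markers: dict = field(default_factory=dict)     # cell_type -> {gene -> mean}
    dispersion: float = 0.3             # NB: var = mu + dispersion * mu^2
    libsize_log_sd: float = 0.35
    batch_log_sd: float = 0.2           # per-batch per-gene log-normal factor
    volume_log_mean: float = np.log(500.0)
    volume_log_sd: float = 0.45
    plaque: PlaqueConfig | None = None
    effects: list = field(default_factory=list)
    states: list = field(default_factory=list)
    subclusters: dict = field(default_factory=dict)  # cell_type -> [SubclusterSpec]
    spillover_rate: float = 0.0
    spillover_k: int = 3
    localized_markers: list = field(default_factory=list)


class ConfigError(ValueError):
    pass


def validate_config(config: SimulationConfig) -> None:
    if not config.samples:
        raise ConfigError("empty sample list")
    for s in config.samples:
        if s.genotype not in GENOTYPES:
            raise ConfigError(f"unknown genotype {s.genotype!r}")
    for i, a in enumerate(config.regions):
        for b in config.regions[i + 1:]:
            if a.overlaps(b):
                raise ConfigError(f"regions {a.name!r} and {b.name!r} overlap")
    for ct, per_region in config.densities.items():
        for region, d in per_region.items():
            if d < 0:
                raise ConfigError(f"negative density for {ct}/{region}")
    if config.dispersion < 0:
        raise ConfigError("dispersion must be > 0")
    if not 0.0 <= config.spillover_rate <= 0.5:
        raise ConfigError("spillover rate must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "little")


def gene_panel(config: SimulationConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Gene names and the baseline mean table (genes x cell types).

    Marker genes named in ``config.markers`` get their configured mean in
    their own cell type and ``marker_off_mean`` elsewhere; the rest of the
    panel is filled with background genes whose per-(gene, type) means are
    log-normal draws from a panel RNG derived from the master seed only.
    """
    marker_names: list[str] = []
    for ct in config.cell_types:
        for g in config.markers.get(ct, {}):
            if g not in marker_names:
                marker_names.append(g)
    n_background = config.n_genes - len(marker_names)
    if n_background < 0:
        raise ConfigError("more marker genes than panel slots")
    background = [f"G{i:03d}" for i in range(n_background)]
    genes = np.array(marker_names + background, dtype=object)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _stable_hash("panel")]))
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                             size=(len(genes), len(config.cell_types))))
    base = np.clip(base, config.baseline_floor, 20.0)
    baseline = pd.DataFrame(base, index=genes, columns=list(config.cell_types))
    for j, g in enumerate(marker_names):
        baseline.iloc[j, :] = config.marker_off_mean
        for ct in config.cell_types:
            if g in config.markers.get(ct, {}):
                baseline.loc[g, ct] = config.markers[ct][g]
    # genes carrying injected effects are guaranteed expressed in their target
    # type, as a real targeted panel would ensure for genes of interest
    for e in config.effects:
        if e.gene in baseline.index and e.cell_type in baseline.columns:
            baseline.loc[e.gene, e.cell_type] = max(baseline.loc[e.gene, e.cell_type], 1.0)
    return genes, baseline


def derive_annotation(config: SimulationConfig) -> ExpressionAnnotation:
    """Reference-style expression annotation consistent with the panel.

    A gene counts as expressed in a type when its baseline mean exceeds the
    marker off-type level, which mimics a trimmed-mean > 0 atlas criterion.
    """
    genes, baseline = gene_panel(config)
    threshold = config.marker_off_mean * 1.5
    expressed = baseline > threshold
    glial = [g for ct in GLIAL_TYPES for g in config.markers.get(ct, {})]
    dam = sorted({g for st in config.states if st.state_name == "DAM"
                  for g, e in st.signature.items() if e > 0})
    daa = sorted({g for st in config.states if st.state_name == "DAA"
                  for g, e in st.signature.items() if e > 0})
    return ExpressionAnnotation(
        expressed=expressed,
        glial_markers=sorted(set(glial)),
        dam_markers=dam,
        daa_markers=daa,
        localized_subcluster_markers=list(config.localized_markers),
    )


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthLog:
    """Machine-readable record of everything the generator injected.

    ``state_genes`` lists, per cell type, the disease-state signature genes:
    their expression genuinely varies with plaque distance (and hence with
    genotype) through the state mechanism, so recovery scoring treats them as
    state-driven rather than false discoveries.
    """
    effects: pd.DataFrame       # gene, cell_type, kind, target, contrast, effect
    cell_truth: pd.DataFrame    # cell_id, state, subcluster
    state_genes: dict = field(default_factory=dict)   # cell_type -> [genes]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": self.effects.to_dict(orient="records"),
            "cell_truth": self.cell_truth.to_dict(orient="list"),
            "state_genes": {k: list(v) for k, v in self.state_genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLog":
        payload = json.loads(Path(path).read_text())
        eff = pd.DataFrame(payload["effects"],
                           columns=["gene", "cell_type", "kind", "target",
                                    "contrast", "effect"])
        eff["target"] = eff["target"].apply(tuple)
        return cls(eff, pd.DataFrame(payload["cell_truth"]),
                   payload.get("state_genes", {}))

    def expected_log2fc(self, contrast: str) -> pd.Series:
        """Expected log2 fold change per gene for an analysis contrast string.

        Understands ``{ct}:{A}_vs_{B}`` (genotype pairs),
        ``{ct}:{region}_vs_rest``, ``{ct}:proximal_vs_distal`` and
        ``{ct}:distance-slope`` (slope per 100 um).
        """
        ct, _, rest = contrast.partition(":")
        out: dict[str, float] = {}
        for _, e in self.effects.iterrows():
            if e["cell_type"] != ct:
                continue
            val = 0.0
            if rest == "distance-slope" and e["kind"] == "distance":
                val = e["effect"]
            elif rest == "proximal_vs_distal" and e["kind"] == "proximal":
                val = e["effect"]
            elif rest.endswith("_vs_rest") and e["kind"] == "region":
                region = rest[: -len("_vs_rest")]
                if e["target"] and e["target"][0] == region:
                    val = e["effect"]
            elif "_vs_" in rest and e["kind"] == "genotype":
                a, _, b = rest.partition("_vs_")
                if a in GENOTYPES and b in GENOTYPES:
                    val = e["effect"] * ((a in e["target"]) - (b in e["target"]))
            if val != 0.0:
                out[e["gene"]] = out.get(e["gene"], 0.0) + val
        return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _stable_hash(sample_id)]))


def _batch_factors(config: SimulationConfig, genes: np.ndarray) -> dict[str, np.ndarray]:
    """Per-batch per-gene log-normal expression factors (shared across samples)."""
    batches = sorted({s.batch_id for s in config.samples})
    out = {}
    for b in batches:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _stable_hash("batch:" + b)]))
        out[b] = np.exp(rng.normal(0.0, config.batch_log_sd, size=len(genes)))
    return out


def simulate_dataset(config: SimulationConfig):
    """Draw one dataset; returns ``(cells, counts, plaques, truth_log)``."""
    validate_config(config)
    genes, baseline = gene_panel(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    batch_factors = _batch_factors(config, genes)

    cell_frames, plaque_frames, count_blocks = [], [], []
    truth_states, truth_subclusters, truth_cell_ids = [], [], []

    for spec in config.samples:
        rng = _sample_rng(config.seed, spec.sample_id)

        # --- cells: spatial Poisson per region x type ------------------------
        xs, ys, cts, regions = [], [], [], []
        for region in config.regions:
            for ct in config.cell_types:
                dens = config.densities.get(ct, {}).get(region.name, 0.0)
                n = rng.poisson(dens * region.area)
                if n == 0:
                    continue
                xs.append(rng.uniform(region.x0, region.x1, n))
                ys.append(rng.uniform(region.y0, region.y1, n))
                cts.extend([ct] * n)
                regions.extend([region.name] * n)
        n_cells = sum(len(a) for a in xs)
        x = np.concatenate(xs) if xs else np.empty(0)
        y = np.concatenate(ys) if ys else np.empty(0)
        cell_type = np.array(cts, dtype=object)
        region_lab = np.array(regions, dtype=object)
        volume = np.exp(rng.normal(config.volume_log_mean, config.volume_log_sd, n_cells))
        cell_ids = np.array([f"{spec.sample_id}_c{i:06d}" for i in range(n_cells)], dtype=object)

        # --- plaques ---------------------------------------------------------
        px, py, psize = [], [], []
        if config.plaque is not None:
            factor = config.plaque.genotype_factors.get(spec.genotype, 0.0)
            for region in config.regions:
                lam = config.plaque.intensity.get(region.name, 0.0) * factor * region.area
                n = rng.poisson(lam) if lam > 0 else 0
                if n == 0:
                    continue
                px.append(rng.uniform(region.x0, region.x1, n))
                py.append(rng.uniform(region.y0, region.y1, n))
                psize.append(np.exp(rng.normal(config.plaque.size_log_mean,
                                               config.plaque.size_log_sd, n)))
        px = np.concatenate(px) if px else np.empty(0)
        py = np.concatenate(py) if py else np.empty(0)
        psize = np.concatenate(psize) if psize else np.empty(0)
        plaque_ids = np.array([f"{spec.sample_id}_p{i:04d}" for i in range(len(px))], dtype=object)

        if len(px) and n_cells:
            tree = cKDTree(np.column_stack([px, py]))
            dist, _ = tree.query(np.column_stack([x, y]), k=1)
        else:
            dist = np.full(n_cells, np.inf)

        # --- subclusters and disease states ----------------------------------
        subcluster = np.array([None] * n_cells, dtype=object)
        for ct, specs in config.subclusters.items():
            idx = np.flatnonzero(cell_type == ct)
            if len(idx) == 0:
                continue
            weights = np.array([sc.genotype_weights.get(spec.genotype, 0.0) for sc in specs])
            if weights.sum() <= 0:
                continue
            probs = weights / weights.sum()
            names = [sc.name for sc in specs]
            subcluster[idx] = rng.choice(names, size=len(idx), p=probs)

        state = np.array(["none"] * n_cells, dtype=object)
        for st in config.states:
            idx = np.flatnonzero(cell_type == st.cell_type)
            if len(idx) == 0:
                continue
            p = st.max_prob * np.exp(-dist[idx] / st.decay_um)
            p[~np.isfinite(dist[idx])] = 0.0
            active = rng.random(len(idx)) < p
            state[idx] = np.where(active, st.state_name, "homeostatic")

        # --- expression ------------------------------------------------------
        log2_shift = np.zeros((n_cells, len(genes)))
        for e in config.effects:
            j = gene_pos.get(e.gene)
            if j is None:
                raise ConfigError(f"effect on unknown gene {e.gene!r}")
            rows = cell_type == e.cell_type
            if e.kind == "genotype":
                if spec.genotype in e.target:
                    log2_shift[rows, j] += e.effect
            elif e.kind == "region":
                log2_shift[rows & (region_lab == e.target[0]), j] += e.effect
            elif e.kind == "proximal":
                log2_shift[rows & (dist < 100.0), j] += e.effect
            elif e.kind == "distance":
                sel = rows & (dist < 100.0)
                log2_shift[sel, j] += e.effect * dist[sel] / 100.0
            else:
                raise ConfigError(f"unknown effect kind {e.kind!r}")
        for st in config.states:
            rows = state == st.state_name
            if not rows.any():
                continue
            for g, shift in st.signature.items():
                log2_shift[rows, gene_pos[g]] += shift

        base = baseline.loc[:, cell_type].to_numpy().T if n_cells else np.zeros((0, len(genes)))
        lib = np.exp(rng.normal(-config.libsize_log_sd ** 2 / 2.0,
                                config.libsize_log_sd, n_cells))
        mu = base * lib[:, None] * np.exp2(log2_shift) * batch_factors[spec.batch_id][None, :]

        if config.dispersion > 1e-8:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, config.dispersion * mu)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)

        if config.spillover_rate > 0 and n_cells > 1:
            k = min(config.spillover_k, n_cells - 1)
            tree = cKDTree(np.column_stack([x, y]))
            _, nbr = tree.query(np.column_stack([x, y]), k=k + 1)
            received = np.zeros_like(counts)
            for col in range(1, k + 1):
                received += rng.binomial(counts[nbr[:, col]], config.spillover_rate)
            counts = counts + received

        cell_frames.append(pd.DataFrame({
            "cell_id": cell_ids, "x": x, "y": y, "volume": volume,
            "cell_type": cell_type, "subcluster": subcluster,
            "region": region_lab, "genotype": spec.genotype,
            "sample_id": spec.sample_id, "batch_id": spec.batch_id,
        }))
        plaque_frames.append(pd.DataFrame({
            "plaque_id": plaque_ids, "x": px, "y": py, "size": psize,
            "sample_id": spec.sample_id,
        }))
        count_blocks.append(sp.csr_matrix(counts.astype(np.int64)))
        truth_states.extend(state)
        truth_subclusters.extend(subcluster)
        truth_cell_ids.extend(cell_ids)

    cells = pd.concat(cell_frames, ignore_index=True)
    plaques = pd.concat(plaque_frames, ignore_index=True)
    counts = sp.vstack(count_blocks).tocsr() if count_blocks else sp.csr_matrix((0, len(genes)))
    cm = CountMatrix(counts, genes, cells["cell_id"].to_numpy(object))

    effects = pd.DataFrame(
        [{"gene": e.gene, "cell_type": e.cell_type, "kind": e.kind,
          "target": tuple(e.target), "contrast": e.contrast(), "effect": e.effect}
         for e in config.effects],
        columns=["gene", "cell_type", "kind", "target", "contrast", "effect"])
    state_genes: dict[str, list[str]] = {}
    for st in config.states:
        state_genes.setdefault(st.cell_type, [])
        state_genes[st.cell_type] = sorted(set(state_genes[st.cell_type]) | set(st.signature))
    truth = TruthLog(
        effects=effects,
        cell_truth=pd.DataFrame({
            "cell_id": truth_cell_ids,
            "state": truth_states,
            "subcluster": [s if s is not None else "" for s in truth_subclusters],
        }),
        state_genes=state_genes,
    )
    return cells, cm, plaques, truth


def expected_cell_count(config: SimulationConfig) -> pd.DataFrame:
    """Expected cells per region x cell type in one sample (density x area)."""
    validate_config(config)
    rows = []
    for region in config.regions:
        for ct in config.cell_types:
            dens = config.densities.get(ct, {}).get(region.name, 0.0)
            rows.append({"region": region.name, "cell_type": ct,
                         "expected": dens * region.area})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default study-like configuration
# ---------------------------------------------------------------------------

DEFAULT_MARKERS = {
    "Microglia": {"Cx3cr1": 6.0, "Tmem119": 5.0, "P2ry12": 5.0, "Hexb": 7.0,
                  "Itgax": 0.4, "Cst7": 0.4, "Csf1": 0.8, "Apoe": 2.0},
    "Astrocyte": {"Slc1a3": 7.0, "Aqp4": 6.0, "Gfap": 2.0, "C4b": 0.8, "Clu": 3.0},
    "Oligodendrocyte": {"Plp1": 8.0, "Mbp": 8.0, "Sox10": 4.0},
    "ExNeuron": {"Slc17a7": 8.0, "Satb2": 5.0},
    "InNeuron": {"Gad1": 7.0, "Gad2": 6.0},
}

DAM_SIGNATURE = {"Itgax": 3.0, "Cst7": 3.0, "Csf1": 2.0, "Apoe": 1.5,
                 "P2ry12": -1.5, "Tmem119": -1.0}
DAA_SIGNATURE = {"Gfap": 2.0, "C4b": 2.0, "Clu": 1.5}

DEFAULT_REGIONS = [
    RegionSpec("neocortex", 0, 0, 1000, 1000),
    RegionSpec("hippocampus", 1050, 0, 2050, 1000),
    RegionSpec("thalamus", 2100, 0, 3100, 1000),
    RegionSpec("CC", 0, 1050, 1000, 2050),
    RegionSpec("striatum", 1050, 1050, 2050, 2050),
    RegionSpec("hypothalamus", 2100, 1050, 3100, 2050),
]

DEFAULT_DENSITIES = {
    "ExNeuron": 2.0e-4,
    "InNeuron": 0.7e-4,
    "Oligodendrocyte": 1.0e-4,
    "Astrocyte": 0.7e-4,
    "Microglia": 0.6e-4,
}

DEFAULT_PLAQUE_INTENSITY = {
    "neocortex": 3.5e-5, "hippocampus": 3.0e-5, "thalamus": 2.0e-5,
    "CC": 5.5e-5, "striatum": 1.5e-5, "hypothalamus": 1.0e-5,
}


def default_samples(n_per_genotype: int = 4, n_batches: int = 3) -> list[SampleSpec]:
    samples = []
    for i in range(n_per_genotype):
        batch = f"B{i % n_batches + 1}"
        for g in GENOTYPES:
            samples.append(SampleSpec(f"{g}_{i + 1}", g, batch))
    return samples


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-like default: 4 genotypes x 3 samples, 3 batches, 6 regions,
    300-gene panel, plaques in 5xFAD carriers, DAM/DAA activation near
    plaques, genotype-biased microglial subclusters, and a small set of
    injected effects in every contrast family."""
    densities = {ct: {r.name: d for r in DEFAULT_REGIONS}
                 for ct, d in DEFAULT_DENSITIES.items()}
    effects = [
        Effect("G010", "ExNeuron", "genotype", 1.0, AMYLOID_GENOTYPES),
        Effect("G011", "ExNeuron", "genotype", -1.0, AMYLOID_GENOTYPES),
        Effect("G012", "InNeuron", "genotype", 1.0, ("Trem2R47H", "Trem2R47H_5xFAD")),
        Effect("G013", "Microglia", "genotype", 1.0, ("5xFAD", "Trem2R47H_5xFAD")),
        Effect("G020", "ExNeuron", "region", 1.0, ("hippocampus",)),
        Effect("G021", "Oligodendrocyte", "region", 1.0, ("CC",)),
        Effect("G030", "Microglia", "proximal", 1.0),
        Effect("G031", "Astrocyte", "proximal", 1.0),
        Effect("G040", "Microglia", "distance", -1.0),
    ]
    states = [
        StateConfig("Microglia", "DAM", max_prob=0.9, decay_um=50.0,
                    signature=dict(DAM_SIGNATURE)),
        StateConfig("Astrocyte", "DAA", max_prob=0.6, decay_um=50.0,
                    signature=dict(DAA_SIGNATURE)),
    ]
    subclusters = {
        "Microglia": [
            SubclusterSpec("Micro_homeo", {g: 1.0 for g in GENOTYPES}),
            SubclusterSpec("Micro_act", {"WT": 0.15, "Trem2R47H": 0.15,
                                         "5xFAD": 1.0, "Trem2R47H_5xFAD": 1.0}),
        ],
    }
    cfg = SimulationConfig(
        seed=seed,
        samples=default_samples(),
        regions=list(DEFAULT_REGIONS),
        cell_types=list(DEFAULT_DENSITIES),
        densities=densities,
        markers={k: dict(v) for k, v in DEFAULT_MARKERS.items()},
        plaque=PlaqueConfig(intensity=dict(DEFAULT_PLAQUE_INTENSITY)),
        effects=effects,
        states=states,
        subclusters=subclusters,
        localized_markers=["G021"],
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    return cfg
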