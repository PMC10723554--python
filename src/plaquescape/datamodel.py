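"""Typed tables for plaque-proximity spatial transcriptomics and their on-disk formats.

The dataset is a triplet of aligned tables:

* a per-cell metadata table (:func:`validate_cells`) with slice-local spatial
  coordinates in micrometers, segmented cell volume, cell-type / subcluster /
  region labels, and the design metadata (genotype, sample, batch);
* a cells x genes integer count matrix (:class:`CountMatrix`), stored as a
  MatrixMarket triplet with two sidecar name lists;
* a table of detected amyloid plaques (:func:`validate_plaques`) with centroid
  coordinates and size.

All coordinates live in a per-sample frame: slices are analyzed independently
and never registered to a common atlas space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

#: Closed genotype vocabulary: wild type, the TREM2 R47H risk variant, the
#: 5xFAD amyloidosis model, and the combined line.
GENOTYPES = ("WT", "Trem2R47H", "5xFAD", "Trem2R47H_5xFAD")

#: Genotypes carrying the 5xFAD transgenes, i.e. the plaque-bearing ones.
AMYLOID_GENOTYPES = ("5xFAD", "Trem2R47H_5xFAD")

CELL_COLUMNS = (
    "cell_id", "x", "y", "volume", "cell_type", "subcluster",
    "region", "genotype", "sample_id", "batch_id",
)
PLAQUE_COLUMNS = ("plaque_id", "x", "y", "size", "sample_id")


class SchemaError(ValueError):
    """A table violates the documented schema."""


# ---------------------------------------------------------------------------
# Count matrix container
# ---------------------------------------------------------------------------

class CountMatrix:
    """Cells x genes matrix of non-negative integer transcript counts.

    Rows are aligned one-to-one, in order, with a validated cell table.
    """

    def __init__(self, counts, gene_names: Sequence[str], cell_ids: Sequence[str]):
        counts = sp.csr_matrix(counts)
        if counts.nnz and counts.data.min() < 0:
            raise SchemaError("counts contain negative entries")
        if not np.issubdtype(counts.dtype, np.integer):
            if counts.nnz and np.any(counts.data != np.floor(counts.data)):
                raise SchemaError("counts contain non-integer entries")
            counts = counts.astype(np.int64)
        self.counts: sp.csr_matrix = counts.astype(np.int64)
        self.gene_names = np.asarray(gene_names, dtype=object)
        self.cell_ids = np.asarray(cell_ids, dtype=object)
        if counts.shape != (len(self.cell_ids), len(self.gene_names)):
            raise SchemaError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise SchemaError("duplicate gene names")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise SchemaError("duplicate cell ids in count matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total transcripts per cell (row sums)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, index) -> "CountMatrix":
        """Row subset by positional indices or a boolean mask; keeps order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(self.counts[index], self.gene_names, self.cell_ids[index])

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(self.counts[:, index], self.gene_names[index], self.cell_ids)

    def gene_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[n] for n in names], dtype=int)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.n_cells} cells x {self.n_genes} genes, nnz={self.counts.nnz})"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cell metadata table.

    Enforces: unique cell ids, finite coordinates, positive volumes, the closed
    genotype vocabulary, and a consistent sample -> (genotype, batch) mapping.
    Returns a copy with a fresh integer index and string-typed label columns.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns and c not in ("subcluster", "region")]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    out = cells.copy().reset_index(drop=True)
    for col in ("subcluster", "region"):
        if col not in out.columns:
            out[col] = None
        out[col] = pd.Series(
            [str(v) if pd.notna(v) else None for v in out[col]],
            index=out.index, dtype=object)
    for col in ("cell_id", "cell_type", "genotype", "sample_id", "batch_id"):
        out[col] = out[col].astype(str)
    for col in ("x", "y", "volume"):
        out[col] = pd.to_numeric(out[col]).astype(float)

    dup = out["cell_id"][out["cell_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate cell ids: {sorted(set(dup))[:5]}")
    if not np.isfinite(out[["x", "y"]].to_numpy(float)).all():
        raise SchemaError("non-finite cell coordinates")
    if (out["volume"].to_numpy(float) <= 0).any():
        raise SchemaError("non-positive cell volumes")
    bad_geno = sorted(set(out["genotype"]) - set(GENOTYPES))
    if bad_geno:
        raise SchemaError(f"unknown genotypes: {bad_geno}; allowed: {list(GENOTYPES)}")
    per_sample = out.groupby("sample_id")[["genotype", "batch_id"]].nunique()
    inconsistent = per_sample[(per_sample > 1).any(axis=1)].index.tolist()
    if inconsistent:
        raise SchemaError(f"samples mapped to multiple genotypes/batches: {inconsistent}")
    return out[list(CELL_COLUMNS)]


def validate_plaques(plaques: pd.DataFrame, cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a plaque table; optionally cross-check against a cell table.

    Plaques found in samples without 5xFAD transgenes are biologically
    implausible and raise a warning (not an error: detection false positives
    are a real phenomenon the pipeline must be able to represent).
    """
    missing = [c for c in PLAQUE_COLUMNS if c not in plaques.columns]
    if missing:
        raise SchemaError(f"plaque table missing columns: {missing}")
    out = plaques.copy().reset_index(drop=True)
    for col in ("plaque_id", "sample_id"):
        out[col] = out[col].astype(str)
    for col in ("x", "y", "size"):
        out[col] = pd.to_numeric(out[col]).astype(float)
    dup = out["plaque_id"][out["plaque_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate plaque ids: {sorted(set(dup))[:5]}")
    if len(out) and (out["size"].to_numpy(float) <= 0).any():
        raise SchemaError("non-positive plaque sizes")
    if cells is not None and len(out):
        sample_geno = cells.drop_duplicates("sample_id").set_index("sample_id")["genotype"]
        unknown = sorted(set(out["sample_id"]) - set(sample_geno.index))
        if unknown:
            raise SchemaError(f"plaques in samples absent from cell table: {unknown}")
        non_amyloid = sample_geno[~sample_geno.isin(AMYLOID_GENOTYPES)].index
        odd = sorted(set(out["sample_id"]) & set(non_amyloid))
        if odd:
            warnings.warn(
                f"plaques reported in non-5xFAD samples: {odd}", stacklevel=2
            )
    return out[list(PLAQUE_COLUMNS)]


def align_counts(cells: pd.DataFrame, cm: CountMatrix) -> CountMatrix:
    """Reorder count-matrix rows to the cell table's order; error on mismatch."""
    cell_set = set(cells["cell_id"])
    count_set = set(cm.cell_ids)
    only_counts = sorted(count_set - cell_set)
    only_cells = sorted(cell_set - count_set)
    if only_counts or only_cells:
        raise SchemaError(
            "cell id mismatch between metadata and counts; "
            f"only in counts: {only_counts[:5]}; only in metadata: {only_cells[:5]}"
        )
    pos = {c: i for i, c in enumerate(cm.cell_ids)}
    order = np.array([pos[c] for c in cells["cell_id"]], dtype=int)
    if np.array_equal(order, np.arange(len(order))):
        return cm
    return cm.subset_cells(order)


# ---------------------------------------------------------------------------
# Expression annotation (reference-atlas derived)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAnnotation:
    """Gene x cell-type boolean annotation plus the marker lists used by filters.

    ``expressed.loc[gene, cell_type]`` is True when reference atlases report the
    gene as expressed in that cell type. Marker lists drive the neuronal filter
    (glial identity markers plus disease-associated microglia / astrocyte
    signatures) and the spatial-confound filter (markers of spatially localized
    subclusters).
    """

    expressed: pd.DataFrame
    glial_markers: list[str] = field(default_factory=list)
    dam_markers: list[str] = field(default_factory=list)
    daa_markers: list[str] = field(default_factory=list)
    localized_subcluster_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expressed.dtypes.ne(bool).any():
            raise SchemaError("expression annotation must be boolean")
        if self.expressed.index.duplicated().any():
            raise SchemaError("duplicate genes in annotation")

    def covers(self, genes: Iterable[str], cell_type: str) -> list[str]:
        """Return the genes *not* covered by the annotation for ``cell_type``."""
        if cell_type not in self.expressed.columns:
            return list(genes)
        return [g for g in genes if g not in self.expressed.index]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    validate_cells(cells).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cells(path: str | Path) -> pd.DataFrame:
    return validate_cells(pd.read_csv(path, dtype={"cell_id": str, "sample_id": str, "batch_id": str}))


def write_plaques(plaques: pd.DataFrame, path: str | Path) -> None:
    validate_plaques(plaques).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_plaques(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plaque_id": str, "sample_id": str})
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=float if c in ("x", "y", "size") else str)
                           for c in PLAQUE_COLUMNS})
    return validate_plaques(df)


def write_counts(cm: CountMatrix, matrix_path: str | Path,
                 genes_path: str | Path, cells_path: str | Path) -> None:
    """MatrixMarket integer triplet plus one-column CSV name lists."""
    scipy.io.mmwrite(str(matrix_path), cm.counts.tocoo(), field="integer")
    pd.DataFrame({"gene": cm.gene_names}).to_csv(genes_path, index=False)
    pd.DataFrame({"cell_id": cm.cell_ids}).to_csv(cells_path, index=False)


def read_counts(matrix_path: str | Path, genes_path: str | Path,
                cells_path: str | Path) -> CountMatrix:
    mat = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, dtype=str)["gene"].to_numpy(dtype=object)
    cell_ids = pd.read_csv(cells_path, dtype=str)["cell_id"].to_numpy(dtype=object)
    return CountMatrix(mat, genes, cell_ids)


def write_dataset(out_dir: str | Path, cells: pd.DataFrame, cm: CountMatrix,
                  plaques: pd.DataFrame) -> dict[str, Path]:
    """Write the dataset triplet into ``out_dir`` with canonical file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out_dir / "cells.csv",
        "matrix": out_dir / "counts.mtx",
        "genes": out_dir / "genes.csv",
        "cell_ids": out_dir / "cell_ids.csv",
        "plaques": out_dir / "plaques.csv",
    }
    write_cells(cells, paths["cells"])
    write_counts(cm, paths["matrix"], paths["genes"], paths["cell_ids"])
    write_plaques(plaques, paths["plaques"])
    return paths


def read_dataset(in_dir: str | Path) -> tuple[pd.DataFrame, CountMatrix, pd.DataFrame]:
    """Read and cross-validate the dataset triplet written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    cells = read_cells(in_dir / "cells.csv")
    cm = read_counts(in_dir / "counts.mtx", in_dir / "genes.csv", in_dir / "cell_ids.csv")
    plaques = read_plaques(in_dir / "plaques.csv")
    validate_plaques(plaques, cells)
    cm = align_counts(cells, cm)
    return cells, cm, plaques


def write_annotation(ann: ExpressionAnnotation, csv_path: str | Path,
                     markers_path: str | Path) -> None:
    df = ann.expressed.astype(int)
    df.index.name = "gene"
    df.to_csv(csv_path)
    with open(markers_path, "w") as fh:
        yaml.safe_dump(
            {
                "glial_markers": list(ann.glial_markers),
                "dam_markers": list(ann.dam_markers),
                "daa_markers": list(ann.daa_markers),
                "localized_subcluster_markers": list(ann.localized_subcluster_markers),
            },
            fh, sort_keys=True,
        )


def read_annotation(csv_path: str | Path, markers_path: str | Path) -> ExpressionAnnotation:
    df = pd.read_csv(csv_path, index_col="gene").astype(bool)
    with open(markers_path) as fh:
        markers = yaml.safe_load(fh) or {}
    return ExpressionAnnotation(
        expressed=df,
        glial_markers=list(markers.get("glial_markers", [])),
        dam_markers=list(markers.get("dam_markers", [])),
        daa_markers=list(markers.get("daa_markers", [])),
        localized_subcluster_markers=list(markers.get("localized_subcluster_markers", [])),
    )


# ---------------------------------------------------------------------------
# DE result convention
# ---------------------------------------------------------------------------

DE_COLUMNS = ("gene", "log2fc", "se", "pvalue", "padj", "significant", "contrast", "n", "method")


def de_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble a differential-expression result table with canonical columns."""
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            DE_COLUMNS, (str, float, float, float, float, bool, str, int, str))})
    df = pd.DataFrame(rows)
    for col in DE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[list(DE_COLUMNS)]
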