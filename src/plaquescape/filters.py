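"""Annotation-based post-hoc filtering of differential-expression results.

Imaging-based segmentation assigns some transcripts to the wrong cell
(overlapping processes, phagocytosis, boundary errors), so genes strongly
induced in one cell type can appear differentially expressed in its spatial
neighbors — the classic example being an astrocyte gene like Gfap "called" in
neurons. These filters remove such rows from finished DE tables using a
reference expression annotation; they never alter the statistics, and every
removal is recorded in a ledger so the operation is auditable and reversible.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import ExpressionAnnotation


def _split(result: pd.DataFrame, remove_reason: dict[str, str]):
    """Partition a DE table into kept rows and a removal ledger."""
    removed_mask = result["gene"].isin(remove_reason)
    kept = result[~removed_mask].reset_index(drop=True)
    ledger = result[removed_mask][["gene", "contrast"]].copy()
    ledger["reason"] = [remove_reason[g] for g in ledger["gene"]]
    return kept, ledger.reset_index(drop=True)


def filter_glial_de(result: pd.DataFrame, annotation: ExpressionAnnotation,
                    cell_type: str):
    """Keep only genes annotated as expressed in the glial cell type tested.

    Every gene in the result must be covered by the annotation for
    ``cell_type``; an uncovered gene is a hard error (the annotation is
    required to span the panel). Returns ``(kept, ledger)``.
    """
    if result.empty:
        return result.copy(), _empty_ledger()
    if cell_type not in annotation.expressed.columns:
        raise KeyError(f"cell type {cell_type!r} not present in annotation")
    missing = annotation.covers(result["gene"], cell_type)
    if missing:
        raise KeyError(f"genes missing from annotation: {sorted(missing)[:5]}")
    expressed = annotation.expressed[cell_type]
    reasons = {g: "not-expressed-in-type" for g in result["gene"] if not expressed.loc[g]}
    return _split(result, reasons)


def filter_neuronal_de(result: pd.DataFrame, annotation: ExpressionAnnotation):
    """Drop glial identity markers and DAM/DAA signature genes from neuronal DE.

    Reason precedence when a gene sits in several lists:
    glial-marker > dam-marker > daa-marker. Returns ``(kept, ledger)``.
    """
    if result.empty:
        return result.copy(), _empty_ledger()
    reasons: dict[str, str] = {}
    for marker_list, reason in (
        (annotation.daa_markers, "daa-marker"),
        (annotation.dam_markers, "dam-marker"),
        (annotation.glial_markers, "glial-marker"),
    ):
        for g in marker_list:
            reasons[g] = reason
    reasons = {g: r for g, r in reasons.items() if g in set(result["gene"])}
    return _split(result, reasons)


def filter_spatial_confounds(result: pd.DataFrame, localized_subcluster_markers):
    """Drop genes that mark spatially localized subclusters (e.g. ventral
    hippocampus subpopulations), whose apparent DE tracks section composition
    rather than biology. Returns ``(kept, ledger)``."""
    if result.empty:
        return result.copy(), _empty_ledger()
    reasons = {g: "spatial-confound" for g in localized_subcluster_markers
               if g in set(result["gene"])}
    return _split(result, reasons)


def _empty_ledger() -> pd.DataFrame:
    return pd.DataFrame({"gene": pd.Series(dtype=str),
                         "contrast": pd.Series(dtype=str),
                         "reason": pd.Series(dtype=str)})
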