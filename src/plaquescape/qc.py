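"""Cell-level quality control and normalization.

QC removes segmentation artifacts: cells with volume above 1800 um^3 (merged
or mis-segmented objects) or with fewer than 50 assigned transcripts (debris,
partial cells). Comparisons are strict, so a cell at exactly 1800 um^3 or
exactly 50 transcripts survives.

Normalization is library-size scaling to a common target followed by
log(1 + x); downstream DE works on counts (pseudobulk / NB offsets), so this
normalized layer exists for inspection and distance summaries, not inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import CountMatrix

MAX_VOLUME = 1800.0     # um^3
MIN_TRANSCRIPTS = 50


def filter_cells(
    cells: pd.DataFrame,
    cm: CountMatrix,
    max_volume: float = MAX_VOLUME,
    min_transcripts: int = MIN_TRANSCRIPTS,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Remove cells with volume > ``max_volume`` or library size < ``min_transcripts``.

    Survivor order is preserved in both tables; the result may be empty.
    Idempotent: filtering a filtered dataset changes nothing.
    """
    if len(cells) != cm.n_cells:
        raise ValueError("cell table and count matrix are not aligned")
    libsize = cm.library_sizes()
    keep = (cells["volume"].to_numpy(float) <= max_volume) & (libsize >= min_transcripts)
    return cells[keep].reset_index(drop=True), cm.subset_cells(keep)


def normalize_counts(cm: CountMatrix, target_sum: float | None = None) -> np.ndarray:
    """Library-size normalize to ``target_sum`` then log1p (natural log).

    ``target_sum`` defaults to the median library size, computed on the input.
    Rows with zero counts map to zero vectors. Returns a dense cells x genes
    array of normalized expression.
    """
    libsize = cm.library_sizes().astype(float)
    if target_sum is None:
        nonzero = libsize[libsize > 0]
        target_sum = float(np.median(nonzero)) if len(nonzero) else 1.0
    scale = np.divide(target_sum, libsize, out=np.zeros_like(libsize), where=libsize > 0)
    scaled = sp.diags(scale) @ cm.counts
    return np.log1p(np.asarray(scaled.todense()))
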