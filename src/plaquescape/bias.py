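"""Genotype-composition bias scoring for subclusters and activation states.

A subcluster drawn evenly from all four genotypes would show 25% from each
after correcting for how many cells each genotype contributed overall. The
classification rule flags a subcluster as enriched in one genotype when its
normalized proportion exceeds 33%, or in an allowed genotype *pair* when the
combined proportion exceeds 60% (50% being uniform). Only the four pairs
sharing a genetic factor are eligible — {WT, Trem2R47H}, {5xFAD,
Trem2R47H;5xFAD}, {WT, 5xFAD}, {Trem2R47H, Trem2R47H;5xFAD} — because the
diagonal pairs (e.g. WT together with the double mutant) have no shared
biology to attribute the enrichment to. Subclusters holding under 5% of the
cells are excluded before any classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import GENOTYPES
from .mixedlm import fit_random_intercept

SINGLE_THRESHOLD = 0.33
PAIR_THRESHOLD = 0.60
MIN_SIZE_FRACTION = 0.05

#: Pairs sharing a genetic factor; the two "diagonal" pairs are never reported.
ALLOWED_PAIRS = (
    ("WT", "Trem2R47H"),
    ("5xFAD", "Trem2R47H_5xFAD"),
    ("WT", "5xFAD"),
    ("Trem2R47H", "Trem2R47H_5xFAD"),
)


def genotype_proportions(cells: pd.DataFrame,
                         subcluster_col: str = "subcluster") -> pd.DataFrame:
    """Genotype-normalized composition of each subcluster.

    For subcluster s and genotype g with n_{s,g} member cells out of N_g total
    cells of that genotype in the input, the rate r_{s,g} = n_{s,g} / N_g is
    renormalized across genotypes to p_{s,g} = r_{s,g} / sum_g' r_{s,g'}, so
    each row sums to 1 and 0.25 everywhere means a perfectly uniform draw.
    The caller is expected to pass the cells of a single cell type.
    """
    counts = (cells.groupby([subcluster_col, "genotype"], observed=True)
              .size().unstack(fill_value=0))
    for g in GENOTYPES:
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[list(GENOTYPES)]
    totals = cells.groupby("genotype", observed=True).size()
    zero = [g for g in GENOTYPES if totals.get(g, 0) == 0]
    if zero:
        raise ValueError(f"genotypes with zero cells: {zero}")
    rates = counts / np.array([totals[g] for g in GENOTYPES])
    props = rates.div(rates.sum(axis=1), axis=0)
    out = props.reset_index().rename(columns={subcluster_col: "subcluster"})
    sizes = cells.groupby(subcluster_col, observed=True).size()
    out["n_cells"] = sizes.loc[out["subcluster"]].to_numpy()
    out["size_fraction"] = out["n_cells"] / len(cells)
    return out


def classify_bias(
    bias: pd.DataFrame,
    single_threshold: float = SINGLE_THRESHOLD,
    pair_threshold: float = PAIR_THRESHOLD,
    min_size_fraction: float = MIN_SIZE_FRACTION,
) -> pd.DataFrame:
    """Attach enrichment classifications to a genotype-proportion table.

    All threshold comparisons are strict ("exceeds"). A subcluster smaller
    than ``min_size_fraction`` of the cells is excluded and never labeled.
    When both a single genotype and a pair trigger, the single-genotype label
    wins; among multiple triggering candidates the largest proportion wins.
    """
    out = bias.copy()
    classifications, excluded = [], []
    for _, row in out.iterrows():
        if row["size_fraction"] < min_size_fraction:
            classifications.append(None)
            excluded.append(True)
            continue
        excluded.append(False)
        p = {g: float(row[g]) for g in GENOTYPES}
        singles = [(v, g) for g, v in p.items() if v > single_threshold]
        if singles:
            classifications.append(f"enriched:{max(singles)[1]}")
            continue
        pairs = [(p[a] + p[b], (a, b)) for a, b in ALLOWED_PAIRS
                 if p[a] + p[b] > pair_threshold]
        if pairs:
            best = max(pairs)[1]
            classifications.append(f"enriched:{best[0]}+{best[1]}")
            continue
        classifications.append("unbiased")
    out["excluded"] = excluded
    out["classification"] = classifications
    return out


def state_region_proportions(
    cells: pd.DataFrame,
    states: pd.Series,
    positive_state: str,
    genotype_pair: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region activation-state proportions and a genotype contrast on them.

    ``states`` is aligned to ``cells.index`` (e.g. DAM vs homeostatic labels
    for microglia). The first table holds, per (region, sample), the fraction
    of cells in ``positive_state`` plus per-region/genotype across-sample mean
    and standard error. When ``genotype_pair`` is given, the second table
    tests the genotype difference per region with the same random-intercept
    (batch) mixed model used for pseudobulk DE, on the per-sample proportions.
    """
    df = cells.copy()
    df["_state"] = states.loc[df.index].astype(str)
    df = df[df["region"].notna()]
    grp = df.groupby(["region", "sample_id"], observed=True)
    per = grp.agg(
        n_cells=("_state", "size"),
        n_positive=("_state", lambda s: int((s == positive_state).sum())),
        genotype=("genotype", "first"),
        batch_id=("batch_id", "first"),
    ).reset_index()
    per = per[per["n_cells"] > 0]
    per["proportion"] = per["n_positive"] / per["n_cells"]

    summary = (per.groupby(["region", "genotype"], observed=True)["proportion"]
               .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                    n_samples="size")
               .reset_index())
    per = per.merge(summary, on=["region", "genotype"], how="left")

    tests = []
    if genotype_pair is not None:
        alt, ref = genotype_pair
        for region, sub in per.groupby("region", observed=True):
            sub = sub[sub["genotype"].isin(genotype_pair)]
            if (sub["genotype"] == alt).sum() < 2 or (sub["genotype"] == ref).sum() < 2:
                continue
            X = np.column_stack([np.ones(len(sub)), (sub["genotype"] == alt).astype(float)])
            fit = fit_random_intercept(sub["proportion"].to_numpy(), X,
                                       sub["batch_id"].to_numpy())
            tests.append({
                "region": region, "contrast": f"{alt}_vs_{ref}",
                "difference": float(fit.coef[1]), "se": float(fit.se[1]),
                "pvalue": float(fit.pvalue[1]), "n_samples": int(len(sub)),
                "method": fit.method,
            })
    tests_df = pd.DataFrame(tests, columns=["region", "contrast", "difference",
                                            "se", "pvalue", "n_samples", "method"])
    return per, tests_df
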