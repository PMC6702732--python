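"""Abundance (log2 RPKM) matrices and species-composition filtering.

RPKM = count * 1e9 / (contig length in nt * library size); the heatmap value is
log2(RPKM + pseudocount). Species rows failing the read-count or frequency
threshold are pooled into a per-pool "other" fraction so the plotted fractions
still sum to one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rpkm_matrix(
    read_counts: pd.DataFrame,
    contig_lengths: pd.Series | dict,
    library_sizes: pd.Series | dict,
    pseudocount: float = 1.0,
    neg_inf_sentinel: float = -30.0,
) -> pd.DataFrame:
    """log2(RPKM + pseudocount) per contig (rows) per pool (columns).

    With pseudocount 0, zero counts give -inf, clamped to ``neg_inf_sentinel``
    so heatmaps stay finite.
    """
    lengths = pd.Series(contig_lengths).reindex(read_counts.index)
    libs = pd.Series(library_sizes).reindex(read_counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing contig lengths for {list(lengths[lengths.isna()].index)}")
    if libs.isna().any():
        raise ValueError(f"missing library sizes for {list(libs[libs.isna()].index)}")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = read_counts.astype(float) * 1e9
    rpkm = rpkm.div(lengths, axis=0).div(libs, axis=1)
    with np.errstate(divide="ignore"):
        values = np.log2(rpkm + pseudocount)
    return values.replace(-np.inf, neg_inf_sentinel)


def species_composition(
    species_counts: pd.DataFrame,
    min_reads: int = 100,
    min_freq: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the read-count + frequency filter to per-pool species counts.

    ``species_counts`` is long-form with columns pool_id, species, read_count.
    Returns the annotated rows (frequency, passes_filter; both thresholds
    inclusive) and the per-pool combined fraction of failing rows, so that per
    pool: passing frequencies + other_fraction == 1.
    """
    required = {"pool_id", "species", "read_count"}
    if not required.issubset(species_counts.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    if (species_counts["read_count"] < 0).any():
        raise ValueError("negative read counts")
    totals = species_counts.groupby("pool_id")["read_count"].sum()
    if (totals == 0).any():
        empty = list(totals[totals == 0].index)
        raise ValueError(f"pool(s) with zero total reads: {empty}")
    rows = species_counts.copy()
    rows["frequency"] = rows["read_count"] / rows["pool_id"].map(totals)
    rows["passes_filter"] = (rows["read_count"] >= min_reads) & (rows["frequency"] >= min_freq)
    other = (
        rows.loc[~rows["passes_filter"]]
        .groupby("pool_id")["frequency"]
        .sum()
        .reindex(totals.index, fill_value=0.0)
    )
    other.name = "other_fraction"
    return rows, other


def collapse_otus_to_species(
    otu_counts: pd.DataFrame, species_column: str = "species"
) -> pd.DataFrame:
    """Sum OTU-level rows (pool_id, species, read_count) to species level."""
    return (
        otu_counts.groupby(["pool_id", species_column], as_index=False)["read_count"]
        .sum()
        .rename(columns={species_column: "species"})
    )
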