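"""Strand-specific small-RNA size profiles and their z-score normalization.

A profile counts aligned reads in a (size, strand) grid: sizes 15-35 nt by
default, positive then negative strand, flattened to a 42-cell vector ordered
p15..p35, m15..m35. Profiles with fewer than 100 in-range reads are dropped
before any downstream comparison, and each retained profile is converted to
frequencies and standardized to mean 0 / sd 1 (population sd over the cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import SmallRnaAlignment

logger = logging.getLogger(__name__)

DEFAULT_SIZE_RANGE = (15, 35)


def cell_labels(size_range: tuple[int, int] = DEFAULT_SIZE_RANGE) -> list[str]:
    lo, hi = size_range
    return [f"p{s}" for s in range(lo, hi + 1)] + [f"m{s}" for s in range(lo, hi + 1)]


@dataclass
class SizeStrandProfile:
    """Read counts per (size, strand) cell for one contig.

    ``counts`` holds the positive-strand sizes first, then the negative-strand
    sizes, both in ascending size order.
    """

    contig_id: str
    counts: np.ndarray
    pool_id: str | None = None
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        n = 2 * (hi - lo + 1)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (n,):
            raise ValueError(f"expected {n} cells for size range {self.size_range}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_sizes(self) -> int:
        return self.size_range[1] - self.size_range[0] + 1

    def frequencies(self) -> np.ndarray:
        if self.total_reads == 0:
            raise ValueError(f"profile {self.contig_id} has no in-range reads")
        return self.counts / self.total_reads


@dataclass
class ZProfile:
    """z-score-normalized frequency vector of one profile.

    Unless degenerate (constant frequencies), values have mean 0 and population
    sd 1 over the full cell vector.
    """

    contig_id: str
    values: np.ndarray
    degenerate: bool = False
    pool_id: str | None = None
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def compute_profile(
    alignments: Iterable[SmallRnaAlignment],
    contig_id: str,
    pool_id: str | None = None,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> SizeStrandProfile:
    """Count alignments of ``contig_id`` into the (size, strand) grid.

    Reads with length outside the size range contribute to neither the cells
    nor the total.
    """
    lo, hi = size_range
    n_sizes = hi - lo + 1
    counts = np.zeros(2 * n_sizes, dtype=np.int64)
    for a in alignments:
        if a.contig_id != contig_id:
            continue
        if not lo <= a.read_length <= hi:
            continue
        offset = 0 if a.strand == "+" else n_sizes
        counts[offset + a.read_length - lo] += 1
    return SizeStrandProfile(contig_id, counts, pool_id=pool_id, size_range=size_range)


def compute_profiles(
    alignments: Sequence[SmallRnaAlignment],
    contig_ids: Sequence[str],
    pool_by_contig: Mapping[str, str | None] | None = None,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> list[SizeStrandProfile]:
    """Profile every contig in one pass over the alignment list."""
    lo, hi = size_range
    n_sizes = hi - lo + 1
    index = {cid: i for i, cid in enumerate(contig_ids)}
    counts = np.zeros((len(contig_ids), 2 * n_sizes), dtype=np.int64)
    for a in alignments:
        i = index.get(a.contig_id)
        if i is None or not lo <= a.read_length <= hi:
            continue
        offset = 0 if a.strand == "+" else n_sizes
        counts[i, offset + a.read_length - lo] += 1
    pools = pool_by_contig or {}
    return [
        SizeStrandProfile(cid, counts[i], pool_id=pools.get(cid), size_range=size_range)
        for cid, i in index.items()
    ]


def filter_profiles(
    profiles: Sequence[SizeStrandProfile], min_reads: int = 100
) -> list[SizeStrandProfile]:
    """Keep profiles with at least ``min_reads`` in-range reads (inclusive)."""
    kept = [p for p in profiles if p.total_reads >= min_reads]
    n_dropped = len(profiles) - len(kept)
    if n_dropped:
        logger.info("filter_profiles: dropped %d/%d profiles below %d reads", n_dropped, len(profiles), min_reads)
    return kept


def zscore(profile: SizeStrandProfile, per_strand: bool = False) -> ZProfile:
    """Standardize the profile's frequency vector to mean 0, population sd 1.

    With ``per_strand`` each strand's half is standardized separately. A
    constant frequency vector cannot be standardized; it yields an all-zero
    vector with the ``degenerate`` flag set.
    """
    f = profile.frequencies()
    if per_strand:
        halves = []
        degenerate = True
        n = profile.n_sizes
        for half in (f[:n], f[n:]):
            sd = half.std()
            if sd == 0:
                halves.append(np.zeros_like(half))
            else:
                degenerate = False
                halves.append((half - half.mean()) / sd)
        values = np.concatenate(halves)
    else:
        sd = f.std()  # population sd: the cells are the whole distribution
        degenerate = sd == 0
        values = np.zeros_like(f) if degenerate else (f - f.mean()) / sd
    return ZProfile(
        profile.contig_id,
        values,
        degenerate=bool(degenerate),
        pool_id=profile.pool_id,
        size_range=profile.size_range,
    )


def strand_fraction(profile: SizeStrandProfile) -> float:
    """Fraction of in-range reads on the positive strand."""
    total = profile.total_reads
    if total == 0:
        raise ValueError(f"profile {profile.contig_id} has no in-range reads")
    return float(profile.counts[: profile.n_sizes].sum()) / total


def profiles_to_frame(profiles: Sequence[SizeStrandProfile]) -> pd.DataFrame:
    """Tabulate profiles as contig x (cells + total), the TSV export layout."""
    if not profiles:
        return pd.DataFrame(columns=cell_labels() + ["pool_id", "total"])
    size_range = profiles[0].size_range
    rows = {p.contig_id: p.counts for p in profiles}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cell_labels(size_range))
    frame.index.name = "contig_id"
    frame["pool_id"] = [p.pool_id if p.pool_id is not None else "" for p in profiles]
    frame["total"] = [p.total_reads for p in profiles]
    return frame


def zprofiles_to_frame(zprofiles: Sequence[ZProfile]) -> pd.DataFrame:
    if not zprofiles:
        return pd.DataFrame(columns=cell_labels())
    size_range = zprofiles[0].size_range
    frame = pd.DataFrame.from_dict(
        {z.contig_id: z.values for z in zprofiles}, orient="index", columns=cell_labels(size_range)
    )
    frame.index.name = "contig_id"
    return frame
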