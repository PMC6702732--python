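"""Contig-level quality gates: length filter, greedy redundancy collapse, ORF tallies.

The redundancy collapse is a transparent desk-scale substitute for k-mer
accelerated clustering tools: pairwise identity comes from a semi-global
alignment of the shorter sequence against the best-scoring window of the
longer (match +1, mismatch -1, gap -2), both orientations tried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .seqio import Contig, reverse_complement

ORF_STATUSES = ("complete", "partial_technical", "fragmented_frameshifted", "short_orf")


def filter_by_length(contigs: Sequence[Contig], min_len_exclusive: int = 500) -> list[Contig]:
    """Keep contigs strictly longer than ``min_len_exclusive``."""
    return [c for c in contigs if c.length > min_len_exclusive]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # the longer sequence is the target; its overhangs (gaps in the query row,
    # "deletions" in Bio.Align naming) are free at both ends
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _identity_one_orientation(shorter: str, longer: str) -> tuple[float, float]:
    alignment = _ALIGNER.align(longer, shorter)[0]
    target_row = alignment[0]
    query_row = alignment[1]
    # trim the free target overhangs: columns where the query row is gapped
    # at either end are outside the aligned region
    first = next(i for i, ch in enumerate(query_row) if ch != "-")
    last = len(query_row) - next(i for i, ch in enumerate(reversed(query_row)) if ch != "-")
    cols = last - first
    matches = sum(
        1 for t, q in zip(target_row[first:last], query_row[first:last]) if t == q and q != "-"
    )
    identity = matches / cols if cols else 0.0
    coverage = cols / len(shorter)
    return identity, coverage


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Best (identity, coverage-of-shorter) over both orientations.

    identity = matches / aligned columns; coverage = aligned columns / shorter
    length (internal gaps can push coverage slightly above 1).
    """
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    fwd = _identity_one_orientation(shorter, longer)
    rev = _identity_one_orientation(reverse_complement(shorter), longer)
    return max(fwd, rev, key=lambda t: t[0])


@dataclass
class RedundancyCluster:
    representative: str
    members: list[str] = field(default_factory=list)
    identity: dict[str, float] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)


def collapse_redundancy(
    contigs: Sequence[Contig],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.90,
) -> list[RedundancyCluster]:
    """Greedy longest-first clustering by pairwise identity/coverage.

    Each contig joins the first existing representative it matches at
    identity >= identity_threshold over >= coverage_threshold of the shorter
    sequence, else founds its own cluster. The clusters partition the input.
    Ties in length break lexicographically by id for determinism.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    seq_of = {c.id: c.sequence for c in contigs}
    clusters: list[RedundancyCluster] = []
    for contig in ordered:
        placed = False
        for cluster in clusters:
            ident, cov = pairwise_identity(contig.sequence, seq_of[cluster.representative])
            if ident >= identity_threshold and cov >= coverage_threshold:
                cluster.members.append(contig.id)
                cluster.identity[contig.id] = ident
                cluster.coverage[contig.id] = cov
                placed = True
                break
        if not placed:
            clusters.append(
                RedundancyCluster(
                    representative=contig.id,
                    members=[contig.id],
                    identity={contig.id: 1.0},
                    coverage={contig.id: 1.0},
                )
            )
    return clusters


@dataclass(frozen=True)
class OrfRecord:
    contig_id: str
    orf_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in ORF_STATUSES:
            raise ValueError(f"ORF {self.orf_id}: status {self.status!r} not in {ORF_STATUSES}")


@dataclass(frozen=True)
class OrfSummary:
    n_contigs: int
    n_orfs: int
    orfs_per_contig_mean: float | None
    functional_contigs: int
    nonfunctional_contigs: int
    empty: bool = False


def summarize_orf_status(
    orf_records: Sequence[OrfRecord], contigs: Iterable[Contig] | Iterable[str]
) -> OrfSummary:
    """Tally ORFs per contig and flag non-functional contigs.

    A contig is non-functional if it carries any fragmented/frameshifted ORF,
    or if all of its ORFs are short ORFs. The mean is reported to one decimal.
    """
    contig_ids = {c.id if isinstance(c, Contig) else str(c) for c in contigs}
    for rec in orf_records:
        if rec.contig_id not in contig_ids:
            raise ValueError(f"ORF {rec.orf_id} references unknown contig {rec.contig_id!r}")
    if not contig_ids:
        return OrfSummary(0, 0, None, 0, 0, empty=True)

    statuses: dict[str, set[str]] = {}
    for rec in orf_records:
        statuses.setdefault(rec.contig_id, set()).add(rec.status)
    nonfunctional = {
        cid
        for cid, st in statuses.items()
        if "fragmented_frameshifted" in st or st == {"short_orf"}
    }
    mean = round(len(orf_records) / len(contig_ids), 1)
    return OrfSummary(
        n_contigs=len(contig_ids),
        n_orfs=len(orf_records),
        orfs_per_contig_mean=mean,
        functional_contigs=len(contig_ids) - len(nonfunctional),
        nonfunctional_contigs=len(nonfunctional),
    )
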