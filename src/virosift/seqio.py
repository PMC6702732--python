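"""Sequence and alignment I/O, plus a brute-force read mapper for desk-scale tests.

Internal coordinates are 0-based half-open throughout; SAM conversion happens at
the file boundary. The mapper is exhaustive (every position, both strands) and is
intended as a stand-in for an external aligner on small fixtures only.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

ORIGIN_LABELS = ("virus", "unclassified", "host", "unknown")

#: fixed column order of the plain-TSV alignment dialect
TSV_ALIGNMENT_COLUMNS = ("read_id", "contig_id", "strand", "start0", "read_length", "mismatches")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """An assembled contig with optional origin/pool metadata."""

    id: str
    sequence: str
    origin_label: str = "unknown"
    pool_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.origin_label not in ORIGIN_LABELS:
            raise ValueError(
                f"contig {self.id}: origin_label {self.origin_label!r} not in {ORIGIN_LABELS}"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SmallRead:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()


@dataclass(frozen=True)
class SmallRnaAlignment:
    """One small-RNA read aligned to one contig (0-based half-open start)."""

    read_id: str
    contig_id: str
    strand: str
    start: int
    read_length: int
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.read_length <= 0 or self.mismatches < 0:
            raise ValueError(f"invalid alignment coordinates: {self}")


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | os.PathLike, metadata: Mapping[str, tuple[str, str | None]] | None = None) -> list[Contig]:
    """Load contigs from FASTA; ids must be unique, sequences are uppercased.

    ``metadata`` optionally maps contig_id -> (origin_label, pool_id).
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        origin, pool = "unknown", None
        if metadata is not None and rec.id in metadata:
            origin, pool = metadata[rec.id]
        contigs.append(Contig(rec.id, str(rec.seq), origin_label=origin, pool_id=pool))
    return contigs


def read_fastq(path: str | os.PathLike) -> list[SmallRead]:
    reads: list[SmallRead] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTQ id {rec.id!r} in {path}")
        seen.add(rec.id)
        reads.append(SmallRead(rec.id, str(rec.seq)))
    return reads


def read_contig_metadata(path: str | os.PathLike) -> dict[str, tuple[str, str | None]]:
    """Read a contig metadata/truth TSV; needs contig_id + origin_label, pool_id optional."""
    meta: dict[str, tuple[str, str | None]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "contig_id" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with a 'contig_id' column")
        for row in reader:
            meta[row["contig_id"]] = (
                row.get("origin_label", "unknown") or "unknown",
                row.get("pool_id") or None,
            )
    return meta


def _alignments_from_sam(path: str, known: set[str] | None) -> list[SmallRnaAlignment]:
    out: list[SmallRnaAlignment] = []
    n_indel = 0
    save = pysam.set_verbosity(0)  # silence missing-index warning
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if known is not None and rec.reference_name not in known:
                    raise ValueError(f"alignment references unknown contig {rec.reference_name!r}")
                if rec.cigartuples and any(op not in (0, 7, 8) for op, _ in rec.cigartuples):
                    n_indel += 1  # profiles use read length, not span: skip indel records
                    continue
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                out.append(
                    SmallRnaAlignment(
                        read_id=rec.query_name,
                        contig_id=rec.reference_name,
                        strand="-" if rec.is_reverse else "+",
                        start=rec.reference_start,
                        read_length=len(rec.query_sequence) if rec.query_sequence else rec.query_length,
                        mismatches=int(nm),
                    )
                )
    finally:
        pysam.set_verbosity(save)
    if n_indel:
        logger.info("skipped %d alignment records with indel CIGAR operations", n_indel)
    return out


def _alignments_from_tsv(path: str, known: set[str] | None) -> list[SmallRnaAlignment]:
    out: list[SmallRnaAlignment] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(TSV_ALIGNMENT_COLUMNS) - set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {TSV_ALIGNMENT_COLUMNS}")
        for row in reader:
            if known is not None and row["contig_id"] not in known:
                raise ValueError(f"alignment references unknown contig {row['contig_id']!r}")
            out.append(
                SmallRnaAlignment(
                    read_id=row["read_id"],
                    contig_id=row["contig_id"],
                    strand=row["strand"],
                    start=int(row["start0"]),
                    read_length=int(row["read_length"]),
                    mismatches=int(row["mismatches"]),
                )
            )
    return out


def read_alignments(
    path: str | os.PathLike,
    contigs: Sequence[Contig] | None = None,
    fmt: str | None = None,
    dedupe: bool = False,
) -> list[SmallRnaAlignment]:
    """Load alignments from SAM/BAM or the TSV dialect.

    SAM records that are unmapped (0x4), secondary (0x100) or supplementary
    (0x800) are skipped; POS is converted from 1-based to 0-based. With
    ``dedupe`` on, duplicate (read_id, contig, start, strand) tuples collapse
    to one record.
    """
    path = str(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"": "tsv", ".tsv": "tsv", ".sam": "sam", ".bam": "bam"}.get(ext, "tsv")
    known = {c.id for c in contigs} if contigs is not None else None
    if fmt in ("sam", "bam"):
        aln = _alignments_from_sam(path, known)
    elif fmt == "tsv":
        aln = _alignments_from_tsv(path, known)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if dedupe:
        seen: set[tuple] = set()
        kept = []
        for a in aln:
            key = (a.read_id, a.contig_id, a.start, a.strand)
            if key not in seen:
                seen.add(key)
                kept.append(a)
        aln = kept
    return aln


# ---------------------------------------------------------------------------
# writers


def write_fasta(path: str | os.PathLike, contigs: Iterable[Contig]) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")


def write_fastq(path: str | os.PathLike, reads: Iterable[SmallRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_alignments_tsv(path: str | os.PathLike, alignments: Iterable[SmallRnaAlignment]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_ALIGNMENT_COLUMNS)
        for a in alignments:
            writer.writerow([a.read_id, a.contig_id, a.strand, a.start, a.read_length, a.mismatches])


def write_alignments_sam(
    path: str | os.PathLike,
    alignments: Iterable[SmallRnaAlignment],
    contigs: Sequence[Contig],
) -> None:
    """Write a minimal SAM: QNAME/FLAG/RNAME/POS/MAPQ/CIGAR(full-length M)/SEQ.

    SEQ is stored in reference orientation as SAM requires, so for mismatch-free
    alignments it equals the forward-strand contig substring.
    """
    by_id = {c.id: c for c in contigs}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.id, "LN": c.length} for c in contigs],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in alignments:
            contig = by_id[a.contig_id]
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = fh.header.get_tid(a.contig_id)
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.read_length}M"
            seg.query_sequence = contig.sequence[a.start : a.start + a.read_length]
            seg.query_qualities = pysam.qualitystring_to_array("I" * a.read_length)
            seg.set_tag("NM", a.mismatches)
            fh.write(seg)


# ---------------------------------------------------------------------------
# brute-force mapper


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def naive_map(
    reads: Sequence[SmallRead],
    contigs: Sequence[Contig],
    max_mismatch: int = 1,
) -> list[SmallRnaAlignment]:
    """Exhaustively align each read (and its reverse complement) to every contig.

    All hits with <= max_mismatch mismatches are reported; N never matches.
    Quadratic by design -- use on fixtures, not on real libraries.
    """
    out: list[SmallRnaAlignment] = []
    enc_contigs = [(c.id, _encode(c.sequence)) for c in contigs]
    n_code = ord("N")
    for read in reads:
        variants = [("+", _encode(read.sequence)), ("-", _encode(reverse_complement(read.sequence)))]
        for contig_id, ref in enc_contigs:
            for strand, query in variants:
                L = query.size
                if L > ref.size:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(ref, L)
                mm = ((windows != query) | (windows == n_code) | (query == n_code)).sum(axis=1)
                for start in np.nonzero(mm <= max_mismatch)[0]:
                    out.append(
                        SmallRnaAlignment(
                            read_id=read.id,
                            contig_id=contig_id,
                            strand=strand,
                            start=int(start),
                            read_length=L,
                            mismatches=int(mm[start]),
                        )
                    )
    return out
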