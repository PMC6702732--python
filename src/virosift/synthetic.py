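"""Seeded generator of contigs and small-RNA reads with known size/strand signatures.

Each signature class is a :class:`SignatureModel`: a read-length distribution
over 15-35 nt, a positive-strand fraction, and a reads-per-contig depth. The
bundled defaults emulate three archetypes -- siRNA processing (21 nt peak, both
strands), piRNA-like (23-29 nt, 27-28 nt peak, strand-biased) and broad-size
strand-biased degradation -- so every downstream stage can be exercised with a
known ground truth and no external data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    Contig,
    SmallRead,
    SmallRnaAlignment,
    reverse_complement,
    write_alignments_sam,
    write_alignments_tsv,
    write_fasta,
    write_fastq,
)

SIZE_MIN, SIZE_MAX = 15, 35

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SignatureModel:
    """Generative model of one small-RNA population class."""

    name: str
    size_pmf: Mapping[int, float]
    positive_strand_fraction: float
    reads_per_contig: int = 2000

    def __post_init__(self) -> None:
        if not self.size_pmf:
            raise ValueError(f"{self.name}: empty size_pmf")
        if any(not SIZE_MIN <= s <= SIZE_MAX for s in self.size_pmf):
            raise ValueError(f"{self.name}: size_pmf keys must lie in [{SIZE_MIN},{SIZE_MAX}]")
        if abs(sum(self.size_pmf.values()) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: size_pmf probabilities must sum to 1")
        if not 0.0 <= self.positive_strand_fraction <= 1.0:
            raise ValueError(f"{self.name}: positive_strand_fraction must be in [0,1]")
        if self.reads_per_contig < 1:
            raise ValueError(f"{self.name}: reads_per_contig must be positive")

    @property
    def max_read_length(self) -> int:
        return max(self.size_pmf)

    def sizes_and_probs(self) -> tuple[np.ndarray, np.ndarray]:
        sizes = np.array(sorted(self.size_pmf), dtype=np.int64)
        probs = np.array([self.size_pmf[s] for s in sizes], dtype=float)
        return sizes, probs / probs.sum()


@dataclass(frozen=True)
class TruthRecord:
    contig_id: str
    true_class: str
    pool_id: str
    origin_label: str


def default_models(reads_per_contig: int = 2000) -> dict[str, SignatureModel]:
    """Bundled signature models; calibration choices, overridable via config."""
    uniform = {s: 1.0 / (SIZE_MAX - SIZE_MIN + 1) for s in range(SIZE_MIN, SIZE_MAX + 1)}
    pirna_pmf = {23: 0.05, 24: 0.07, 25: 0.10, 26: 0.15, 27: 0.25, 28: 0.25, 29: 0.13}
    return {
        "sirna": SignatureModel("sirna", {20: 0.10, 21: 0.80, 22: 0.10}, 0.5, reads_per_contig),
        "pirna": SignatureModel("pirna", pirna_pmf, 0.10, reads_per_contig),
        "pirna_positive": SignatureModel("pirna_positive", pirna_pmf, 0.90, reads_per_contig),
        "degradation": SignatureModel("degradation", uniform, 0.20, reads_per_contig),
    }


DEFAULT_ORIGIN_BY_CLASS = {
    "sirna": "virus",
    "pirna": "virus",
    "pirna_positive": "virus",
    "degradation": "host",
}


def simulate_contigs(
    n_per_class: Mapping[str, int],
    length_range: tuple[int, int] = (800, 3000),
    gc: float = 0.5,
    seed: int = 0,
    pools: Sequence[str] = ("pool1",),
    origin_by_class: Mapping[str, str] | None = None,
) -> tuple[list[Contig], list[TruthRecord]]:
    """Draw random contigs per class plus the matching truth table.

    Lengths are uniform over ``length_range``; pools are assigned round-robin
    within each class. Deterministic for a fixed seed.
    """
    lo, hi = length_range
    if not (501 <= lo <= hi <= 50000):
        raise ValueError(f"length_range must lie within [501, 50000], got {length_range}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    for cls, n in n_per_class.items():
        if n < 0:
            raise ValueError(f"negative contig count for class {cls!r}")
    origins = dict(DEFAULT_ORIGIN_BY_CLASS)
    if origin_by_class:
        origins.update(origin_by_class)

    rng = np.random.default_rng(seed)
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs: list[Contig] = []
    truth: list[TruthRecord] = []
    for cls in sorted(n_per_class):
        origin = origins.get(cls, "virus")
        for i in range(n_per_class[cls]):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(_BASES, size=length, p=base_probs))
            pool = pools[i % len(pools)]
            cid = f"{cls}_{i:04d}"
            contigs.append(Contig(cid, seq, origin_label=origin, pool_id=pool))
            truth.append(TruthRecord(cid, cls, pool, origin))
    return contigs, truth


def simulate_reads(
    contigs: Sequence[Contig],
    truth: Sequence[TruthRecord],
    models: Mapping[str, SignatureModel] | None = None,
    seed: int = 0,
    error_rate: float = 0.0,
    read_prefix: str = "r",
) -> tuple[list[SmallRead], list[SmallRnaAlignment]]:
    """Sample reads per contig from its class model; emit reads + true alignments.

    Per read: length ~ size_pmf, strand ~ Bernoulli(positive_strand_fraction),
    start uniform over valid positions. The read sequence is the contig
    substring (reverse-complemented on the negative strand), optionally mutated
    at ``error_rate`` per base.
    """
    models = models if models is not None else default_models()
    class_of = {t.contig_id: t.true_class for t in truth}
    for contig in contigs:
        cls = class_of.get(contig.id)
        if cls is None:
            raise ValueError(f"contig {contig.id} has no truth record")
        if cls not in models:
            raise ValueError(f"no signature model for class {cls!r} (contig {contig.id})")
        if contig.length < models[cls].max_read_length:
            raise ValueError(
                f"contig {contig.id} ({contig.length} nt) shorter than the longest "
                f"read length of model {cls!r} ({models[cls].max_read_length} nt)"
            )

    rng = np.random.default_rng(seed)
    reads: list[SmallRead] = []
    alignments: list[SmallRnaAlignment] = []
    counter = 0
    for contig in contigs:
        model = models[class_of[contig.id]]
        n = model.reads_per_contig
        sizes, probs = model.sizes_and_probs()
        lengths = rng.choice(sizes, size=n, p=probs)
        plus = rng.random(n) < model.positive_strand_fraction
        starts = rng.integers(0, contig.length - lengths + 1)
        for L, is_plus, start in zip(lengths, plus, starts):
            L, start = int(L), int(start)
            mismatches = 0
            sub = contig.sequence[start : start + L]
            if error_rate > 0:
                chars = list(sub)
                for k in range(L):
                    if rng.random() < error_rate:
                        alts = [b for b in "ACGT" if b != chars[k]]
                        chars[k] = alts[int(rng.integers(0, 3))]
                        mismatches += 1
                sub = "".join(chars)
            seq = sub if is_plus else reverse_complement(sub)
            rid = f"{read_prefix}{counter:07d}"
            counter += 1
            reads.append(SmallRead(rid, seq))
            alignments.append(
                SmallRnaAlignment(
                    read_id=rid,
                    contig_id=contig.id,
                    strand="+" if is_plus else "-",
                    start=start,
                    read_length=L,
                    mismatches=mismatches,
                )
            )
    return reads, alignments


def write_truth_table(path: str | os.PathLike, truth: Iterable[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\ttrue_class\tpool_id\torigin_label\n")
        for t in truth:
            fh.write(f"{t.contig_id}\t{t.true_class}\t{t.pool_id}\t{t.origin_label}\n")


def read_truth_table(path: str | os.PathLike) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["contig_id", "true_class", "pool_id", "origin_label"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for line in fh:
            cid, cls, pool, origin = line.rstrip("\n").split("\t")
            out.append(TruthRecord(cid, cls, pool, origin))
    return out


def write_fixture(
    outdir: str | os.PathLike,
    contigs: Sequence[Contig],
    reads: Sequence[SmallRead],
    alignments: Sequence[SmallRnaAlignment],
    truth: Sequence[TruthRecord],
) -> dict[str, str]:
    """Write contigs/reads/alignments/truth to ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "contigs": os.path.join(outdir, "contigs.fasta"),
        "reads": os.path.join(outdir, "reads.fastq"),
        "alignments_tsv": os.path.join(outdir, "alignments.tsv"),
        "alignments_sam": os.path.join(outdir, "alignments.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(paths["contigs"], contigs)
    write_fastq(paths["reads"], reads)
    write_alignments_tsv(paths["alignments_tsv"], alignments)
    write_alignments_sam(paths["alignments_sam"], alignments, contigs)
    write_truth_table(paths["truth"], truth)
    return paths
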