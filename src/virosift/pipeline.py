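"""End-to-end orchestration: qc -> profile -> cluster -> recruit -> control -> abundance.

Configuration is a flat JSON document; every stage writes its table under the
output directory and the run ends with a manifest (inputs, thresholds, seed,
per-stage record counts, output hashes). Reruns with the same config are
byte-identical, so manifest hashes double as a determinism check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, abundance, clustering, profiles, qc, recruit, seqio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    contigs: str
    alignments: str
    outdir: str
    metadata: str | None = None
    min_len: int = 500
    min_reads: int = 100
    corr_threshold: float = 0.9
    identity: float = 0.95
    coverage: float = 0.90
    k: int = 4
    size_min: int = 15
    size_max: int = 35
    species_min_reads: int = 100
    min_freq: float = 0.01
    corr_method: str = "pearson"
    continuity_correction: bool = True
    require_same_pool: bool = True
    collapse: bool = True
    z_enrich: float = 1.0
    bias_threshold: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.min_len < 0 or self.min_reads < 0:
            raise ValueError("thresholds must be non-negative")
        if not -1.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in [-1, 1]")
        if not 0.0 < self.identity <= 1.0 or not 0.0 < self.coverage <= 1.5:
            raise ValueError("identity/coverage thresholds out of range")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.size_min <= self.size_max:
            raise ValueError("invalid size range")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown corr_method {self.corr_method!r}")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest dictionary."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    size_range = (config.size_min, config.size_max)
    manifest: dict = {
        "tool": "virosift",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
    }
    outputs: dict[str, str] = {}

    def out(name: str, filename: str) -> str:
        path = os.path.join(config.outdir, filename)
        outputs[name] = path
        return path

    # ---- load ------------------------------------------------------------
    try:
        metadata = seqio.read_contig_metadata(config.metadata) if config.metadata else None
        contigs = seqio.read_fasta(config.contigs, metadata=metadata)
        alignments = seqio.read_alignments(config.alignments, contigs=contigs)
    except Exception as exc:
        raise StageError("load", exc) from exc
    if config.require_same_pool and any(c.pool_id is None for c in contigs):
        raise StageError(
            "load",
            ValueError(
                "require_same_pool is on but contig pool metadata is missing; "
                "provide a metadata table or disable the pool constraint"
            ),
        )
    manifest["stages"].append({"stage": "load", "contigs": len(contigs), "alignments": len(alignments)})

    # ---- qc --------------------------------------------------------------
    try:
        kept = qc.filter_by_length(contigs, min_len_exclusive=config.min_len)
        if config.collapse:
            clusters = qc.collapse_redundancy(
                kept, identity_threshold=config.identity, coverage_threshold=config.coverage
            )
            representatives = {cl.representative for cl in clusters}
            kept = [c for c in kept if c.id in representatives]
            rows = [
                {"representative": cl.representative, "member": m,
                 "identity": cl.identity[m], "coverage": cl.coverage[m]}
                for cl in clusters
                for m in cl.members
            ]
            pd.DataFrame(rows).to_csv(out("redundancy", "redundancy_clusters.tsv"), sep="\t", index=False)
        logger.info("qc: %d/%d contigs retained", len(kept), len(contigs))
    except Exception as exc:
        raise StageError("qc", exc) from exc
    manifest["stages"].append({"stage": "qc", "retained": len(kept)})

    # ---- profile ---------------------------------------------------------
    try:
        pool_of = {c.id: c.pool_id for c in kept}
        all_profiles = profiles.compute_profiles(
            alignments, [c.id for c in kept], pool_by_contig=pool_of, size_range=size_range
        )
        passing = profiles.filter_profiles(all_profiles, min_reads=config.min_reads)
        profiles.profiles_to_frame(passing).to_csv(out("profiles", "profiles.tsv"), sep="\t")
        zmap = {p.contig_id: profiles.zscore(p) for p in passing}
        fracs = {p.contig_id: profiles.strand_fraction(p) for p in passing}
    except Exception as exc:
        raise StageError("profile", exc) from exc
    manifest["stages"].append(
        {"stage": "profile", "profiled": len(all_profiles), "passing_min_reads": len(passing)}
    )

    origin = {c.id: c.origin_label for c in kept}
    virus_z = [zmap[p.contig_id] for p in passing if origin[p.contig_id] == "virus"]
    query_z = [zmap[p.contig_id] for p in passing if origin[p.contig_id] == "unclassified"]
    host_z = [zmap[p.contig_id] for p in passing if origin[p.contig_id] == "host"]

    # ---- cluster ---------------------------------------------------------
    try:
        model = clustering.cluster_profiles(
            virus_z,
            fracs,
            k=min(config.k, len([z for z in virus_z if not z.degenerate])),
            method=config.corr_method,
            z_enrich=config.z_enrich,
            bias_threshold=config.bias_threshold,
        )
        with open(out("dendrogram", "dendrogram.nwk"), "w") as fh:
            fh.write(model.newick() + "\n")
        pd.DataFrame(
            [
                {"contig_id": cid, "cluster": cl, "signature": model.signatures[cl]}
                for cid, cl in sorted(model.assignments.items())
            ]
        ).to_csv(out("clusters", "clusters.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise StageError("cluster", exc) from exc
    manifest["stages"].append(
        {"stage": "cluster", "profiles": len(virus_z), "k": len(model.signatures),
         "signatures": {str(k): v for k, v in sorted(model.signatures.items())}}
    )

    # ---- recruit ---------------------------------------------------------
    try:
        records = recruit.recruit(
            query_z,
            virus_z,
            model.assignments,
            threshold=config.corr_threshold,
            require_same_pool=config.require_same_pool,
            method=config.corr_method,
        )
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out("recruitment", "recruitment.tsv"), sep="\t", index=False
        )
    except Exception as exc:
        raise StageError("recruit", exc) from exc
    manifest["stages"].append(
        {"stage": "recruit", "queries": len(records), "recruited": sum(r.recruited for r in records)}
    )

    # ---- control ---------------------------------------------------------
    try:
        if host_z:
            control = recruit.reconstruction_control(
                host_z,
                virus_z,
                model.assignments,
                threshold=config.corr_threshold,
                require_same_pool=config.require_same_pool,
                method=config.corr_method,
                signatures=model.signatures,
            )
            payload = {
                "n_host": control.n_host,
                "n_recruited": control.n_recruited,
                "recruitment_rate": control.recruitment_rate,
                "cluster_fractions": {str(k): v for k, v in sorted(control.cluster_fractions.items())},
                "signature_fractions": dict(sorted(control.signature_fractions.items())),
            }
        else:
            payload = {"n_host": 0, "n_recruited": 0, "recruitment_rate": None,
                       "cluster_fractions": {}, "signature_fractions": {}}
        with open(out("control", "control_summary.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise StageError("control", exc) from exc
    manifest["stages"].append({"stage": "control", **{k: payload[k] for k in ("n_host", "n_recruited")}})

    # ---- abundance -------------------------------------------------------
    try:
        kept_ids = {c.id for c in kept}
        pools = sorted({c.pool_id or "pool" for c in kept})
        count_frame = pd.DataFrame(0, index=sorted(kept_ids), columns=pools, dtype=np.int64)
        for a in alignments:
            if a.contig_id in kept_ids:
                count_frame.loc[a.contig_id, pool_of.get(a.contig_id) or "pool"] += 1
        library_sizes = count_frame.sum(axis=0)
        library_sizes[library_sizes == 0] = 1  # empty pools contribute no signal
        lengths = pd.Series({c.id: c.length for c in kept})
        matrix = abundance.rpkm_matrix(count_frame, lengths, library_sizes)
        matrix.to_csv(out("abundance", "abundance_log2_rpkm.tsv"), sep="\t")
    except Exception as exc:
        raise StageError("abundance", exc) from exc
    manifest["stages"].append({"stage": "abundance", "contigs": int(matrix.shape[0]), "pools": int(matrix.shape[1])})

    config.to_json(os.path.join(config.outdir, "config.json"))
    outputs["config"] = os.path.join(config.outdir, "config.json")
    manifest["outputs"] = {name: {"path": path, "sha256": _sha256(path)} for name, path in sorted(outputs.items())}
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
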