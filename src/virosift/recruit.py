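"""Recruit unclassified contigs into virus signature clusters, plus the host control.

A query joins the cluster of its single best-correlated virus profile when the
correlation reaches the threshold (inclusive) and, when required, the two
contigs come from the same sample pool. The reconstruction control replays the
same procedure on host-derived contigs: heavy host recruitment into a signature
class marks that class as non-specific for viral origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .profiles import ZProfile


@dataclass(frozen=True)
class RecruitmentRecord:
    query_contig: str
    best_match_virus: str | None
    correlation: float
    assigned_cluster: int | None
    same_pool: bool
    recruited: bool
    cluster_mean_correlation: float = float("nan")


@dataclass(frozen=True)
class ControlSummary:
    n_host: int
    n_recruited: int
    recruitment_rate: float | None
    cluster_fractions: dict[int, float]
    signature_fractions: dict[str, float]
    records: tuple[RecruitmentRecord, ...]


def _corr_vectors(zprofiles: Sequence[ZProfile], method: str) -> np.ndarray:
    data = np.vstack([z.values for z in zprofiles])
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 1, data)
    # center/scale rows so that correlation is a dot product
    data = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(data, axis=1, keepdims=True)
    norms[norms == 0] = np.nan
    return data / norms


def recruit(
    query_zprofiles: Sequence[ZProfile],
    virus_zprofiles: Sequence[ZProfile],
    virus_assignments: Mapping[str, int],
    threshold: float = 0.9,
    require_same_pool: bool = True,
    method: str = "pearson",
) -> list[RecruitmentRecord]:
    """Assign each query to the cluster of its best-correlated virus profile.

    Correlation >= threshold (inclusive) recruits; with ``require_same_pool``
    only virus profiles from the query's pool are candidates. Queries with no
    candidate or below-threshold best match are emitted with recruited=False.
    """
    if not virus_zprofiles:
        raise ValueError("empty virus profile set")
    missing = [z.contig_id for z in virus_zprofiles if z.contig_id not in virus_assignments]
    if missing:
        raise ValueError(f"virus profiles without cluster assignment: {missing}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    vmat = _corr_vectors(virus_zprofiles, method)
    qmat = (
        _corr_vectors(query_zprofiles, method)
        if query_zprofiles
        else np.zeros((0, vmat.shape[1]))
    )
    corr = np.clip(qmat @ vmat.T, -1.0, 1.0)  # queries x viruses
    virus_pools = np.array([z.pool_id if z.pool_id is not None else "" for z in virus_zprofiles])
    virus_ids = [z.contig_id for z in virus_zprofiles]
    virus_clusters = np.array([virus_assignments[v] for v in virus_ids])

    records: list[RecruitmentRecord] = []
    for qi, query in enumerate(query_zprofiles):
        row = corr[qi].copy()
        if require_same_pool:
            qpool = query.pool_id if query.pool_id is not None else ""
            row[virus_pools != qpool] = np.nan
        if np.all(np.isnan(row)):
            records.append(
                RecruitmentRecord(query.contig_id, None, float("nan"), None, require_same_pool, False)
            )
            continue
        best = int(np.nanargmax(row))
        best_r = float(row[best])
        cluster = int(virus_clusters[best])
        in_cluster = ~np.isnan(row) & (virus_clusters == cluster)
        cluster_mean = float(np.nanmean(row[in_cluster])) if in_cluster.any() else float("nan")
        recruited = best_r >= threshold
        records.append(
            RecruitmentRecord(
                query_contig=query.contig_id,
                best_match_virus=virus_ids[best],
                correlation=best_r,
                assigned_cluster=cluster if recruited else None,
                same_pool=require_same_pool,
                recruited=recruited,
                cluster_mean_correlation=cluster_mean,
            )
        )
    return records


def reconstruction_control(
    host_zprofiles: Sequence[ZProfile],
    virus_zprofiles: Sequence[ZProfile],
    virus_assignments: Mapping[str, int],
    threshold: float = 0.9,
    require_same_pool: bool = True,
    method: str = "pearson",
    signatures: Mapping[int, str] | None = None,
) -> ControlSummary:
    """Recruitment replayed on host contigs, summarized per cluster/signature."""
    records = recruit(
        host_zprofiles,
        virus_zprofiles,
        virus_assignments,
        threshold=threshold,
        require_same_pool=require_same_pool,
        method=method,
    )
    recruited = [r for r in records if r.recruited]
    n_host = len(host_zprofiles)
    cluster_fractions: dict[int, float] = {}
    signature_fractions: dict[str, float] = {}
    if recruited:
        for r in recruited:
            cluster_fractions[r.assigned_cluster] = cluster_fractions.get(r.assigned_cluster, 0) + 1
        for c in list(cluster_fractions):
            cluster_fractions[c] /= len(recruited)
        if signatures is not None:
            for c, frac in cluster_fractions.items():
                sig = signatures.get(c, "unassigned")
                signature_fractions[sig] = signature_fractions.get(sig, 0.0) + frac
    rate = len(recruited) / n_host if n_host else None
    return ControlSummary(
        n_host=n_host,
        n_recruited=len(recruited),
        recruitment_rate=rate,
        cluster_fractions=cluster_fractions,
        signature_fractions=signature_fractions,
        records=tuple(records),
    )
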