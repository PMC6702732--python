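"""Correlation of z-profiles, UPGMA clustering, and rule-based signature labels.

Distance is 1 - correlation. The UPGMA implementation is deliberately explicit
(Lance-Williams average-linkage updates with a fixed tie-breaking rule) so that
merge order is deterministic; its heights are checked against independent
average-linkage implementations in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles import ZProfile

logger = logging.getLogger(__name__)

SIGNATURE_LABELS = (
    "sirna",
    "sirna_pirna_mixed",
    "pirna_positive_biased",
    "pirna_negative_biased",
    "unassigned",
)


def correlation_matrix(
    zprofiles: Sequence[ZProfile], method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlation of z-profile vectors (symmetric, unit diagonal).

    Degenerate profiles are excluded (their z-vector is constant, so the
    correlation is undefined); the exclusion is logged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    usable = [z for z in zprofiles if not z.degenerate]
    dropped = [z.contig_id for z in zprofiles if z.degenerate]
    if dropped:
        logger.info("correlation_matrix: excluded %d degenerate profiles: %s", len(dropped), dropped)
    if len(usable) < 2:
        raise ValueError(f"need at least 2 non-degenerate profiles, have {len(usable)}")
    ids = [z.contig_id for z in usable]
    data = np.vstack([z.values for z in usable])
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 1, data)
    corr = np.corrcoef(data)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)


def correlation_to_distance(corr: pd.DataFrame) -> pd.DataFrame:
    """Distance = 1 - r, in [0, 2], zero diagonal."""
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return dist


def upgma(distance: pd.DataFrame | np.ndarray, ids: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomeration of a square symmetric distance matrix.

    Returns a scipy-style linkage matrix (rows: left id, right id, height,
    size; original leaves are 0..n-1, merges create n, n+1, ...) and the leaf
    id list. Each merge height is the unweighted average pairwise distance
    between the merged groups' leaves. At equal distance the pair with the
    lexicographically smallest (cluster id, cluster id) merges first.
    """
    if isinstance(distance, pd.DataFrame):
        if ids is None:
            ids = list(distance.index)
        distance = distance.to_numpy(dtype=float)
    else:
        distance = np.asarray(distance, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(distance.shape[0])]
    n = distance.shape[0]
    if distance.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(distance, distance.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distance), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 leaves")

    D = distance.astype(float).copy()
    active = list(range(n))            # positions currently in D
    cluster_id = list(range(n))        # scipy-style id per position
    sizes = np.ones(n, dtype=np.int64)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = D[i, j]
                pair = tuple(sorted((cluster_id[i], cluster_id[j])))
                key = (d, pair)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        (d, pair), ai, aj = best
        i, j = active[ai], active[aj]
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams average-linkage update, written into slot i
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (ni * D[i, k] + nj * D[j, k]) / (ni + nj)
        sizes[i] = ni + nj
        Z[step] = [pair[0], pair[1], d, ni + nj]
        cluster_id[i] = n + step
        del active[aj]
    return Z, list(ids)


def cut_clusters(linkage: np.ndarray, ids: Sequence[str], k: int = 4) -> dict[str, int]:
    """Cut the dendrogram into exactly ``k`` groups by undoing the last merges.

    Cluster labels are 1..k in order of first appearance along the leaf list.
    """
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(n + max(0, n - k)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(linkage[step, 0]), int(linkage[step, 1])
        merged = n + step
        parent[find(a)] = merged
        parent[find(b)] = merged

    label_of_root: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for leaf, cid in enumerate(ids):
        root = find(leaf)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        assignments[cid] = label_of_root[root]
    return assignments


def to_newick(linkage: np.ndarray, ids: Sequence[str]) -> str:
    """Render the dendrogram as Newick with ultrametric branch lengths (height/2)."""
    n = len(ids)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: str(ids[i]) for i in range(n)}
    for step in range(n - 1):
        a, b = int(linkage[step, 0]), int(linkage[step, 1])
        h = linkage[step, 2] / 2.0
        la = f"{node[a]}:{h - height[a]:.6g}"
        lb = f"{node[b]}:{h - height[b]:.6g}"
        new = n + step
        node[new] = f"({la},{lb})"
        height[new] = h
        del node[a], node[b]
    (root,) = node.values()
    return root + ";"


def classify_signature(
    mean_z: np.ndarray,
    mean_strand_fraction: float,
    z_enrich: float = 1.0,
    bias_threshold: float = 0.75,
    size_range: tuple[int, int] = (15, 35),
    pirna_band: tuple[int, int] = (23, 29),
) -> str:
    """Label a cluster from its mean z-profile and mean positive-strand fraction.

    Rules, applied in order: 21-nt enrichment on both strands without piRNA-band
    enrichment -> sirna; with it -> sirna_pirna_mixed; piRNA-band enrichment on
    one strand plus matching strand bias -> pirna_{positive,negative}_biased;
    otherwise unassigned.
    """
    mean_z = np.asarray(mean_z, dtype=float)
    lo, hi = size_range
    n_sizes = hi - lo + 1
    if mean_z.shape != (2 * n_sizes,):
        raise ValueError(f"expected {2 * n_sizes}-cell mean z-profile, got {mean_z.shape}")

    def plus_cell(size: int) -> float:
        return mean_z[size - lo]

    def minus_cell(size: int) -> float:
        return mean_z[n_sizes + size - lo]

    band = range(pirna_band[0], pirna_band[1] + 1)
    band_plus = float(np.mean([plus_cell(s) for s in band]))
    band_minus = float(np.mean([minus_cell(s) for s in band]))

    sirna_both = plus_cell(21) >= z_enrich and minus_cell(21) >= z_enrich
    band_enriched = band_plus >= z_enrich or band_minus >= z_enrich
    if sirna_both and not band_enriched:
        return "sirna"
    if sirna_both and band_enriched:
        return "sirna_pirna_mixed"
    if band_plus >= z_enrich and mean_strand_fraction >= bias_threshold:
        return "pirna_positive_biased"
    if band_minus >= z_enrich and mean_strand_fraction <= 1.0 - bias_threshold:
        return "pirna_negative_biased"
    return "unassigned"


@dataclass
class ClusterModel:
    """Dendrogram + cluster memberships + per-cluster signature labels."""

    linkage: np.ndarray
    ids: list[str]
    assignments: dict[str, int]
    signatures: dict[int, str] = field(default_factory=dict)

    def newick(self) -> str:
        return to_newick(self.linkage, self.ids)


def cluster_profiles(
    zprofiles: Sequence[ZProfile],
    strand_fractions: Mapping[str, float],
    k: int = 4,
    method: str = "pearson",
    z_enrich: float = 1.0,
    bias_threshold: float = 0.75,
) -> ClusterModel:
    """Full clustering stage: correlate, UPGMA, cut at k, label signatures."""
    corr = correlation_matrix(zprofiles, method=method)
    linkage, ids = upgma(correlation_to_distance(corr))
    assignments = cut_clusters(linkage, ids, k=k)
    by_id = {z.contig_id: z for z in zprofiles}
    signatures: dict[int, str] = {}
    size_range = zprofiles[0].size_range
    for cluster in sorted(set(assignments.values())):
        members = [cid for cid, c in assignments.items() if c == cluster]
        mean_z = np.mean([by_id[m].values for m in members], axis=0)
        mean_frac = float(np.mean([strand_fractions[m] for m in members]))
        signatures[cluster] = classify_signature(
            mean_z, mean_frac, z_enrich=z_enrich, bias_threshold=bias_threshold, size_range=size_range
        )
    return ClusterModel(linkage=linkage, ids=ids, assignments=assignments, signatures=signatures)
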