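"""Independent brute-force oracles used to cross-check the package's implementations.

These deliberately re-derive each quantity from first principles (textbook
formulas, explicit enumeration, dense dynamic programming) and share no code
with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# 2x2 chi-squared, direct four-cell formula


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> float:
    """Sum over the four cells of (|O-E| - correction)^2 / E with E from margins."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / n
            diff = abs(table[i, j] - expected)
            if yates:
                diff = max(0.0, diff - 0.5)
            stat += diff**2 / expected
    return stat


# ---------------------------------------------------------------------------
# average-linkage agglomeration by explicit leaf-set recomputation


def upgma_heights(distance: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, recomputed from leaf sets.

    At every step the pairwise group distance is recomputed from scratch as the
    mean of all original leaf-to-leaf distances, O(n^3) overall.
    """
    n = distance.shape[0]
    groups: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(groups) > 1:
        best = None
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                d = float(
                    np.mean([distance[x, y] for x in groups[gi] for y in groups[gj]])
                )
                if best is None or d < best[0]:
                    best = (d, gi, gj)
        d, gi, gj = best
        heights.append(d)
        groups[gi] = groups[gi] + groups[gj]
        del groups[gj]
    return heights


# ---------------------------------------------------------------------------
# semi-global alignment by dense dynamic programming

MATCH, MISMATCH, GAP = 1, -1, -2


def semiglobal_identity(shorter: str, longer: str) -> tuple[float, float, float]:
    """(identity, coverage, score) of the shorter sequence aligned globally
    against the best-scoring window of the longer (free longer-end gaps).

    Dense DP with traceback; identity = matches / aligned columns, coverage =
    aligned columns / len(shorter).
    """
    m, n = len(shorter), len(longer)
    q = np.frombuffer(shorter.encode(), dtype=np.uint8)
    t = np.frombuffer(longer.encode(), dtype=np.uint8)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    P = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up (gap in longer), 2 left (gap in shorter)
    H[0, :] = 0
    H[:, 0] = GAP * np.arange(m + 1)
    P[1:, 0] = 1
    offsets = GAP * np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where(t == q[i - 1], MATCH, MISMATCH).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + GAP
        cand = np.maximum(diag, up)
        ptr_du = np.where(diag >= up, 0, 1).astype(np.int8)
        # left-gap chains are a running max because the gap penalty is linear:
        # H[i,j] = GAP*j + max_{k<=j}( base[k] - GAP*k )
        base = np.concatenate(([H[i, 0]], cand))
        running = np.maximum.accumulate(base - offsets)
        row = offsets + running
        row[0] = H[i, 0]
        H[i] = row
        P[i, 1:] = np.where(row[1:] > cand, 2, ptr_du)
    j = int(np.argmax(H[m]))
    score = float(H[m, j])
    i = m
    matches = 0
    cols = 0
    while i > 0:
        ptr = P[i, j]
        cols += 1
        if ptr == 0:
            if shorter[i - 1] == longer[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif ptr == 1:
            i -= 1
        else:
            j -= 1
    identity = matches / cols if cols else 0.0
    coverage = cols / m
    return identity, coverage, score


def best_orientation_identity(a: str, b: str) -> tuple[float, float]:
    """Mirror of the implementation's contract: both strands, best identity wins."""
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    fwd = semiglobal_identity(shorter, longer)[:2]
    rev = semiglobal_identity(revcomp(shorter), longer)[:2]
    return max(fwd, rev, key=lambda t: t[0])
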