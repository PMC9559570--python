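"""Independent reference implementations used only to check the library.

These deliberately use exhaustive strategies (full anti-diagonal enumeration,
full dynamic programming) instead of the library's seeded/accelerated paths.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_ir(seq: str, min_len: int) -> tuple[int, int, int] | None:
    """Exhaustively find the best exact inverted-repeat pair on a circle.

    Enumerates every anti-diagonal of the doubled sequence and every maximal
    exact run of complementary positions on it, keeps pairs that are disjoint
    on the circle, and returns (start_a, start_b, length) with
    start_a <= start_b (mod-n coordinates), maximizing length then minimizing
    the smaller start.  Returns None when no pair of length >= min_len exists.
    """
    n = len(seq)
    s2 = seq + seq
    sv = np.frombuffer(s2.encode(), dtype=np.uint8)
    comp = np.full(256, 0, dtype=np.uint8)
    for x, y in _COMP.items():
        comp[ord(x)] = ord(y)
    cv = comp[sv]
    found: set[tuple[int, int, int]] = set()
    for C in range(4 * n - 3):
        # bounds enforce disjoint copies with >= 1 bp single-copy gap each side
        i_lo = max(0, C - 2 * n + 1, -(-(C + 2 - n) // 2))
        i_hi = min(2 * n, C + 1, C // 2)
        if i_hi - i_lo < min_len:
            continue
        idx = np.arange(i_lo, i_hi)
        m = sv[idx] == cv[C - idx]
        # maximal runs of True
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for rs, re_ in zip(edges[::2], edges[1::2]):
            L = int(re_ - rs)
            if L < min_len:
                continue
            a = int(i_lo + rs)
            b = C + 1 - L - a
            am, bm = a % n, b % n
            found.add((min(am, bm), max(am, bm), L))
    if not found:
        return None
    best = min(found, key=lambda t: (-t[2], t[0]))
    return best


def gotoh_local(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Smith-Waterman-Gotoh local alignment score by full DP.

    Affine gaps with the first gap column costing ``gap_open`` and each
    additional column ``gap_extend``; N matches nothing.
    """
    NEG = -(10**9)
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consuming b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consuming a)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
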