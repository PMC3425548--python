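"""Global alignment kernel behind percent-identity-with-gaps.

The dereplication identity measure needs a pinned, reproducible global
aligner: match +1, mismatch 0, linear gap penalty -1, ties broken toward
fewer gap columns.  Both objectives are folded into a single integer DP by
scoring a match as ``+A`` and a gap column as ``-(A+1)`` with
``A > len(a) + len(b)``: the optimum then maximises the alignment score
first and minimises the gap-column count second, and both quantities are
recoverable from the scalar optimum without a traceback.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _dp(a: np.ndarray, b: np.ndarray, big: np.int64, gap: np.int64) -> np.int64:
    n = b.size
    prev = np.empty(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        prev[j] = gap * j
    for i in range(1, a.size + 1):
        cur[0] = gap * i
        ai = a[i - 1]
        for j in range(1, n + 1):
            best = prev[j - 1] + (big if ai == b[j - 1] else 0)
            up = prev[j] + gap
            if up > best:
                best = up
            left = cur[j - 1] + gap
            if left > best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[n]


def align_stats(a: str, b: str) -> tuple[int, int, int]:
    """Return ``(matches, gap_columns, alignment_length)`` of the optimal
    global alignment (max score, then fewest gaps) of two sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    big = len(a) + len(b) + 1
    c = int(_dp(av, bv, np.int64(big), np.int64(-(big + 1))))
    score = math.ceil(c / big)  # matches - gaps
    gaps = big * score - c
    matches = score + gaps
    length = (len(a) + len(b) + gaps) // 2
    return matches, gaps, length


def percent_identity_with_gaps(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal global alignment,
    gap columns included in the denominator.  Symmetric; 1.0 iff equal."""
    matches, _, length = align_stats(a, b)
    return matches / length
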