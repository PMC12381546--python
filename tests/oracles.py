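"""Independent reference implementations used only by the tests.

Two oracles for affine-gap alignment scores, written from the cost model
directly and sharing no code with the package (whose aligners wrap
Biopython): a pure recursive enumeration over alignment moves (feasible only
for very short sequences) and a plain-Python three-state DP.  The enumeration
cross-validates the DP at tiny sizes; the DP then serves as the oracle at
length 12.  A gap of length L costs open + L * ext.
"""

from __future__ import annotations

NEG = float("-inf")


def enumerate_global(a: str, b: str, match: float, mismatch: float,
                     open_: float, ext: float) -> float:
    """Exhaustive recursion over all global alignments (no memoization)."""

    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):  # a residue against a gap
            cost = ext + (open_ if state != "X" else 0.0)
            best = max(best, cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = ext + (open_ if state != "Y" else 0.0)
            best = max(best, cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


def gotoh_global(a: str, b: str, match: float, mismatch: float,
                 open_: float, ext: float) -> float:
    """Three-state affine DP, end gaps penalized."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap run consuming a
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap run consuming b
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + i * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + j * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + open_ + ext, X[i - 1][j] + ext,
                          Y[i - 1][j] + open_ + ext)
            Y[i][j] = max(M[i][j - 1] + open_ + ext, X[i][j - 1] + open_ + ext,
                          Y[i][j - 1] + ext)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local(a: str, b: str, match: float, mismatch: float,
                open_: float, ext: float) -> float:
    """Smith-Waterman with affine gaps; the empty alignment scores 0."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
            )
            X[i][j] = max(M[i - 1][j] + open_ + ext, X[i - 1][j] + ext,
                          Y[i - 1][j] + open_ + ext)
            Y[i][j] = max(M[i][j - 1] + open_ + ext, X[i][j - 1] + open_ + ext,
                          Y[i][j - 1] + ext)
            best = max(best, M[i][j])
    return best


def enumerate_local(a: str, b: str, match: float, mismatch: float,
                    open_: float, ext: float) -> float:
    """Local score by exhausting all substring pairs with the global
    enumerator (tiny inputs only)."""
    best = 0.0
    for i0 in range(len(a) + 1):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(
                        best,
                        enumerate_global(a[i0:i1], b[j0:j1], match, mismatch,
                                         open_, ext),
                    )
    return best
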