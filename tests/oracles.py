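"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (plain Python,
no reuse of the package's alignment or statistics code paths) so tests can
compare the optimised implementations against slow, obviously-correct
computations.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def sw_score(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Plain O(nm) Smith-Waterman; returns (best score, columns, matches)
    of one optimal local alignment (diag preferred on ties)."""
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            h = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    i, j = bi, bj
    cols = matches = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            cols += 1
            if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT":
                matches += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            cols += 1
            i -= 1
        elif H[i][j] == H[i][j - 1] + gap:
            cols += 1
            j -= 1
        else:
            break
    return best, cols, matches


def sw_best_both_strands(a: str, b: str):
    fwd = sw_score(a, b)
    rev = sw_score(a, rc(b))
    return max(fwd, rev)


def kendall_tau_b_enumeration(x, y) -> float:
    """tau-b by exhaustive enumeration of all pairs with tie corrections."""
    n = len(x)
    conc = disc = ties_x = ties_y = ties_both = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_both += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif (dx > 0) == (dy > 0):
                conc += 1
            else:
                disc += 1
    n_x = conc + disc + ties_y  # pairs untied in x
    n_y = conc + disc + ties_x  # pairs untied in y
    denom = math.sqrt(n_x * n_y)
    if denom == 0:
        raise ZeroDivisionError("all pairs tied")
    return (conc - disc) / denom


def gls_fit(C, X, y):
    """Textbook GLS via explicit inverse: beta, sigma2_ml, loglik."""
    import numpy as np

    C = np.asarray(C, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Ci = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
    r = y - X @ beta
    sigma2 = float(r @ Ci @ r) / n
    loglik = -0.5 * (
        n * math.log(2 * math.pi * sigma2) + math.log(np.linalg.det(C)) + n
    )
    return beta, sigma2, loglik
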