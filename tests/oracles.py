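"""Independent oracles used by the test suite.

Everything here is written from first principles, separately from the
package code paths it checks: a full affine-gap Smith-Waterman dynamic
program with traceback (numba-compiled), brute-force pair counting for the
Mann-Whitney AUC, the textbook expected-count chi-square formula, and an
exhaustive connected-component search.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
GAP_OPEN = 11
GAP_EXTEND = 1

# BLOSUM62 lookup over AA_ORDER, sourced from Biopython (independent of the
# package's aligner backend)
_B62 = substitution_matrices.load("BLOSUM62")
SUBMAT = np.zeros((len(AA_ORDER), len(AA_ORDER)), dtype=np.int64)
for _i, _a in enumerate(AA_ORDER):
    for _j, _b in enumerate(AA_ORDER):
        SUBMAT[_i, _j] = int(_B62[_a][_b])

_NEG = -(10**9)


@njit
def _sw_fill(q, s, submat, open_, ext):
    m, n = q.shape[0], s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    best = 0
    bi = bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - open_
            if E[i, j - 1] - ext > e:
                e = E[i, j - 1] - ext
            E[i, j] = e
            f = H[i - 1, j] - open_
            if F[i - 1, j] - ext > f:
                f = F[i - 1, j] - ext
            F[i, j] = f
            h = H[i - 1, j - 1] + submat[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


@njit
def _sw_traceback(q, s, submat, open_, ext, H, E, F, bi, bj):
    # returns (matches, length) of the traced optimal local alignment
    i, j = bi, bj
    matches = 0
    length = 0
    state = 0  # 0=H, 1=E (gap in query), 2=F (gap in subject)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + submat[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                length += 1
                if q[i - 1] == s[j - 1] and q[i - 1] != 20:  # X never matches
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            length += 1
            if E[i, j] == H[i, j - 1] - open_:
                state = 0
                j -= 1
            else:
                j -= 1
        else:
            length += 1
            if F[i, j] == H[i - 1, j] - open_:
                state = 0
                i -= 1
            else:
                i -= 1
    return matches, length


def sw_oracle(query: str, subject: str):
    """Full Smith-Waterman: (score, matching_residues, alignment_length) or None."""
    q = np.array([AA_ORDER.index(c) for c in query], dtype=np.int64)
    s = np.array([AA_ORDER.index(c) for c in subject], dtype=np.int64)
    H, E, F, best, bi, bj = _sw_fill(q, s, SUBMAT, GAP_OPEN, GAP_EXTEND)
    if best <= 0:
        return None
    matches, length = _sw_traceback(q, s, SUBMAT, GAP_OPEN, GAP_EXTEND, H, E, F, bi, bj)
    return int(best), int(matches), int(length)


def auc_by_pair_counting(group1, group2) -> float:
    """P(group2 value > group1 value) with ties counted one half."""
    wins = 0.0
    for a in group1:
        for b in group2:
            if b > a:
                wins += 1.0
            elif b == a:
                wins += 0.5
    return wins / (len(group1) * len(group2))


def chi2_by_formula(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square from the expected-count formula (no correction)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(stat), dof


def components_by_exhaustive_search(nodes, edges):
    """Connected components by iterative closure over an explicit edge list."""
    comp = {n: frozenset([n]) for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            merged = comp[a] | comp[b]
            if merged != comp[a] or merged != comp[b]:
                for n in merged:
                    comp[n] = merged
                changed = True
    return set(comp.values())


def spearman_by_rank_formula(x, y) -> float:
    """Pearson correlation of midranks, computed explicitly."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
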