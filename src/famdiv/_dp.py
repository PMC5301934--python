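"""Dynamic-programming kernels (numba-jitted).

Two alignment problems are solved here:

* local alignment of a position-specific scoring model against a protein
  (Smith-Waterman-style, affine gaps, three states M/D/I), used by the
  domain and motif scanners;
* global alignment over a precomputed column-pair score matrix (Gotoh),
  used by progressive profile-profile merging.

Kernels fill score and pointer matrices; tracebacks run in plain Python
(they touch O(path) cells only).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# pointer codes
FROM_START = 0
FROM_M = 1
FROM_I = 2
FROM_D = 3


@njit(cache=True)
def fill_local(scores, codes, gap_open, gap_extend):
    """Fill M/D/I matrices for local model-vs-sequence alignment.

    scores: (m, n_codes) per-column per-residue log-odds (bits)
    codes:  (n,) residue codes of the target sequence
    Returns (M, D, I, ptrM, ptrD, ptrI); matrices are (m+1, n+1).
    """
    m = scores.shape[0]
    n = codes.shape[0]
    M = np.full((m + 1, n + 1), NEG)
    D = np.full((m + 1, n + 1), NEG)
    I = np.full((m + 1, n + 1), NEG)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrD = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrI = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # match state: model column i consumes sequence position j
            best = 0.0
            ptr = FROM_START
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
                ptr = FROM_M
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                ptr = FROM_I
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                ptr = FROM_D
            M[i, j] = scores[i - 1, codes[j - 1]] + best
            ptrM[i, j] = ptr
            # delete state: model column i skipped (no sequence char);
            # entering from I opens a fresh gap in the other dimension
            dm = M[i - 1, j] - gap_open
            dd = D[i - 1, j] - gap_extend
            di = I[i - 1, j] - gap_open
            D[i, j] = dm
            ptrD[i, j] = FROM_M
            if dd > D[i, j]:
                D[i, j] = dd
                ptrD[i, j] = FROM_D
            if di > D[i, j]:
                D[i, j] = di
                ptrD[i, j] = FROM_I
            # insert state: sequence position j inserted after model column i
            im = M[i, j - 1] - gap_open
            ii = I[i, j - 1] - gap_extend
            id_ = D[i, j - 1] - gap_open
            I[i, j] = im
            ptrI[i, j] = FROM_M
            if ii > I[i, j]:
                I[i, j] = ii
                ptrI[i, j] = FROM_I
            if id_ > I[i, j]:
                I[i, j] = id_
                ptrI[i, j] = FROM_D
    return M, D, I, ptrM, ptrD, ptrI


@njit(cache=True)
def best_local_score(scores, codes, gap_open, gap_extend):
    """Maximal local alignment score only (no traceback) — calibration path."""
    m = scores.shape[0]
    n = codes.shape[0]
    Mprev = np.full(n + 1, NEG)
    Dprev = np.full(n + 1, NEG)
    Iprev = np.full(n + 1, NEG)
    best_all = 0.0
    for i in range(1, m + 1):
        Mcur = np.full(n + 1, NEG)
        Dcur = np.full(n + 1, NEG)
        Icur = np.full(n + 1, NEG)
        for j in range(1, n + 1):
            best = 0.0
            if Mprev[j - 1] > best:
                best = Mprev[j - 1]
            if Dprev[j - 1] > best:
                best = Dprev[j - 1]
            if Iprev[j - 1] > best:
                best = Iprev[j - 1]
            Mcur[j] = scores[i - 1, codes[j - 1]] + best
            dm = Mprev[j] - gap_open
            dd = Dprev[j] - gap_extend
            di = Iprev[j] - gap_open
            Dcur[j] = max(dm, dd, di)
            im = Mcur[j - 1] - gap_open
            ii = Icur[j - 1] - gap_extend
            id_ = Dcur[j - 1] - gap_open
            Icur[j] = max(im, ii, id_)
            if Mcur[j] > best_all:
                best_all = Mcur[j]
        Mprev = Mcur
        Dprev = Dcur
        Iprev = Icur
    return best_all


@njit(cache=True)
def fill_global(S, gap_open, gap_extend):
    """Gotoh global alignment over score matrix S (L1 x L2).

    Terminal gaps are penalised like internal ones (true global).
    Returns (M, X, Y, ptrM, ptrX, ptrY) where X = gap in second profile
    (consumes rows of S), Y = gap in first profile (consumes columns).
    """
    n1, n2 = S.shape
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)
    Y = np.full((n1 + 1, n2 + 1), NEG)
    ptrM = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)
    ptrX = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)
    ptrY = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
        ptrX[i, 0] = FROM_M if i == 1 else FROM_D
    for j in range(1, n2 + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
        ptrY[0, j] = FROM_M if j == 1 else FROM_I
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            best = M[i - 1, j - 1]
            ptr = FROM_M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = FROM_D
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = FROM_I
            M[i, j] = S[i - 1, j - 1] + best
            ptrM[i, j] = ptr
            xm = M[i - 1, j] - gap_open
            xx = X[i - 1, j] - gap_extend
            xy = Y[i - 1, j] - gap_open
            X[i, j] = xm
            ptrX[i, j] = FROM_M
            if xx > X[i, j]:
                X[i, j] = xx
                ptrX[i, j] = FROM_D
            if xy > X[i, j]:
                X[i, j] = xy
                ptrX[i, j] = FROM_I
            ym = M[i, j - 1] - gap_open
            yy = Y[i, j - 1] - gap_extend
            yx = X[i, j - 1] - gap_open
            Y[i, j] = ym
            ptrY[i, j] = FROM_M
            if yy > Y[i, j]:
                Y[i, j] = yy
                ptrY[i, j] = FROM_I
            if yx > Y[i, j]:
                Y[i, j] = yx
                ptrY[i, j] = FROM_D
    return M, X, Y, ptrM, ptrX, ptrY


def traceback_local(M, ptrM, ptrD, ptrI, i, j):
    """Walk pointers from M[i, j] back to the local start.

    Returns (model_start, seq_start, pairs) where pairs is the list of
    (model_column, seq_position) match states, both 1-based, ascending.
    """
    pairs = [(i, j)]
    state = "M"
    while True:
        if state == "M":
            ptr = ptrM[i, j]
            if ptr == FROM_START:
                break
            i -= 1
            j -= 1
            state = {FROM_M: "M", FROM_I: "I", FROM_D: "D"}[ptr]
            if state == "M":
                pairs.append((i, j))
        elif state == "D":
            ptr = ptrD[i, j]
            i -= 1
            state = {FROM_M: "M", FROM_D: "D", FROM_I: "I"}[ptr]
            if state == "M":
                pairs.append((i, j))
        else:  # I
            ptr = ptrI[i, j]
            j -= 1
            state = {FROM_M: "M", FROM_I: "I", FROM_D: "D"}[ptr]
            if state == "M":
                pairs.append((i, j))
    pairs.reverse()
    return pairs[0][0], pairs[0][1], pairs


def traceback_global(M, X, Y, ptrM, ptrX, ptrY):
    """Recover the global alignment path as a list of (i, j) moves.

    Each element is (i, j) with 0 meaning a gap: (i, 0) consumes row i
    only, (0, j) consumes column j only, (i, j) aligns them. 1-based.
    """
    n1 = M.shape[0] - 1
    n2 = M.shape[1] - 1
    end_scores = (M[n1, n2], X[n1, n2], Y[n1, n2])
    state = "MDI"[int(np.argmax(end_scores))]
    state = {"M": "M", "D": "X", "I": "Y"}[state]
    i, j = n1, n2
    path = []
    while i > 0 or j > 0:
        if state == "M":
            path.append((i, j))
            ptr = ptrM[i, j]
            i -= 1
            j -= 1
            state = {FROM_M: "M", FROM_D: "X", FROM_I: "Y"}[ptr]
        elif state == "X":
            path.append((i, 0))
            ptr = ptrX[i, j]
            i -= 1
            state = {FROM_M: "M", FROM_D: "X", FROM_I: "Y"}[ptr]
        else:
            path.append((0, j))
            ptr = ptrY[i, j]
            j -= 1
            state = {FROM_M: "M", FROM_I: "Y", FROM_D: "X"}[ptr]
    path.reverse()
    return path
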