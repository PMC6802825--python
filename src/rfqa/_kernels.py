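"""Numba-compiled numerical kernels.

These are internal: thin, allocation-light routines behind the public
contact-alignment and TM-score APIs. Pure-python reference oracles used in
the test suite deliberately do not go through this module.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e18


@njit(cache=False)
def gotoh_align(S, gap_open, gap_extend, local):
    """Affine-gap alignment of the rows/columns of similarity matrix S.

    local=True gives Smith-Waterman-style local alignment (empty alignment
    scores 0); local=False gives global alignment with affine end gaps.
    Traceback ties prefer the diagonal (match) over gaps, then the up move.
    Returns (score, ai, bi): 0-based aligned row/column index arrays.
    """
    n, m = S.shape
    H = np.full((n + 1, m + 1), _NEG)
    E = np.full((n + 1, m + 1), _NEG)  # alignment ending in gap consuming B
    F = np.full((n + 1, m + 1), _NEG)  # alignment ending in gap consuming A
    ph = np.zeros((n + 1, m + 1), np.int8)  # 0 stop, 1 diag, 2 up(F), 3 left(E)
    pe = np.zeros((n + 1, m + 1), np.int8)  # 0 open, 1 extend
    pf = np.zeros((n + 1, m + 1), np.int8)
    H[0, 0] = 0.0
    if local:
        for i in range(n + 1):
            H[i, 0] = 0.0
        for j in range(m + 1):
            H[0, j] = 0.0
    else:
        for i in range(1, n + 1):
            F[i, 0] = gap_open + (i - 1) * gap_extend
            pf[i, 0] = 1 if i > 1 else 0
            H[i, 0] = F[i, 0]
            ph[i, 0] = 2
        for j in range(1, m + 1):
            E[0, j] = gap_open + (j - 1) * gap_extend
            pe[0, j] = 1 if j > 1 else 0
            H[0, j] = E[0, j]
            ph[0, j] = 3

    best = 0.0
    bi_ = n
    bj_ = m
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if eo >= ee:
                E[i, j] = eo
                pe[i, j] = 0
            else:
                E[i, j] = ee
                pe[i, j] = 1
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fo >= fe:
                F[i, j] = fo
                pf[i, j] = 0
            else:
                F[i, j] = fe
                pf[i, j] = 1
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if local and h < 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ph[i, j] = p
            if local and h > best:
                best = h
                bi_ = i
                bj_ = j
    if not local:
        best = H[n, m]

    cap = n if n < m else m
    ai = np.empty(cap, np.int64)
    bi = np.empty(cap, np.int64)
    k = 0
    if local and best <= 0.0:
        return 0.0, ai[:0], bi[:0]
    i = bi_
    j = bj_
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        if state == 0:
            p = ph[i, j]
            if p == 0:
                break
            if p == 1:
                ai[k] = i - 1
                bi[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            if pe[i, j] == 0:
                state = 0
            j -= 1
        else:
            if pf[i, j] == 0:
                state = 0
            i -= 1
    # reverse in place
    for r in range(k // 2):
        ai[r], ai[k - 1 - r] = ai[k - 1 - r], ai[r]
        bi[r], bi[k - 1 - r] = bi[k - 1 - r], bi[r]
    return best, ai[:k].copy(), bi[:k].copy()


@njit(cache=False)
def mapping_objective(O, P, ai, bi, sep_tol, gap_open, gap_extend):
    """True (quadratic) contact-alignment objective of a monotone mapping.

    Sum over pairs of aligned contacts of w = o * p / (1 + |Δsep| / sep_tol),
    plus affine gap costs between consecutive aligned pairs (flanks free).
    """
    t = ai.shape[0]
    score = 0.0
    for r in range(t):
        for s in range(r + 1, t):
            o = O[ai[r], ai[s]]
            if o > 0.0:
                p = P[bi[r], bi[s]]
                if p > 0.0:
                    sa = ai[s] - ai[r]
                    sb = bi[s] - bi[r]
                    d = sa - sb
                    if d < 0:
                        d = -d
                    score += o * p / (1.0 + d / sep_tol)
    for r in range(1, t):
        ga = ai[r] - ai[r - 1] - 1
        gb = bi[r] - bi[r - 1] - 1
        if ga > 0:
            score += gap_open + (ga - 1) * gap_extend
        if gb > 0:
            score += gap_open + (gb - 1) * gap_extend
    return score


@njit(cache=False)
def overlap_seed(O, P, sep_tol):
    """Residue-pair seed similarity from contact-neighbourhood overlap."""
    LA = O.shape[0]
    LB = P.shape[0]
    M = np.zeros((LA, LB))
    for i in range(LA):
        for a in range(LB):
            s = 0.0
            for k in range(LA):
                o = O[i, k]
                if o <= 0.0:
                    continue
                da = k - i
                for b in range(LB):
                    p = P[a, b]
                    if p <= 0.0:
                        continue
                    db = b - a
                    if (da > 0) == (db > 0):
                        dd = da - db
                        if dd < 0:
                            dd = -dd
                        s += o * p / (1.0 + dd / sep_tol)
            M[i, a] = 0.5 * s
    return M


@njit(cache=False)
def refine_seed(O, P, ai, bi, sep_tol):
    """Seed similarity induced by the current mapping (double dynamic programming).

    M[i, a] accumulates the weight of contacts (i, k)/(a, b) whose far ends
    k -> b are aligned in the current mapping, on the same chain side.
    """
    LA = O.shape[0]
    LB = P.shape[0]
    M = np.zeros((LA, LB))
    t = ai.shape[0]
    for r in range(t):
        ir = ai[r]
        ar = bi[r]
        for i in range(LA):
            o = O[i, ir]
            if o <= 0.0:
                continue
            da = ir - i
            for a in range(LB):
                p = P[a, ar]
                if p <= 0.0:
                    continue
                db = ar - a
                if (da > 0) == (db > 0):
                    dd = da - db
                    if dd < 0:
                        dd = -dd
                    M[i, a] += o * p / (1.0 + dd / sep_tol)
    return M


@njit(cache=False)
def refine_run(O, P, M0, go, ge, gap_open, gap_extend, sep_tol, iters):
    """One double-DP refinement run from seed matrix M0.

    Repeats local DP alignment and mapping-induced seed refreshing until the
    mapping stops changing or ``iters`` cycles elapse; returns the best
    mapping under the true quadratic objective (with the *nominal* gap
    penalties gap_open/gap_extend; go/ge only steer the DP search).
    """
    best = 0.0
    best_ai = np.empty(0, np.int64)
    best_bi = np.empty(0, np.int64)
    prev_ai = np.empty(0, np.int64)
    prev_bi = np.empty(0, np.int64)
    M = M0
    for _ in range(iters):
        _, ai, bi = gotoh_align(M, go, ge, True)
        if ai.shape[0] == 0:
            break
        true = mapping_objective(O, P, ai, bi, sep_tol, gap_open, gap_extend)
        if true > best + 1e-12:
            best = true
            best_ai = ai
            best_bi = bi
        if ai.shape[0] == prev_ai.shape[0]:
            same = True
            for r in range(ai.shape[0]):
                if ai[r] != prev_ai[r] or bi[r] != prev_bi[r]:
                    same = False
                    break
            if same:
                break
        prev_ai = ai
        prev_bi = bi
        M = refine_seed(O, P, ai, bi, sep_tol)
    return best, best_ai, best_bi


@njit(cache=False)
def _kabsch(P, Q):
    """Optimal rotation/translation mapping P onto Q (least squares)."""
    n = P.shape[0]
    pc = np.zeros(3)
    qc = np.zeros(3)
    for r in range(n):
        for k in range(3):
            pc[k] += P[r, k]
            qc[k] += Q[r, k]
    for k in range(3):
        pc[k] /= n
        qc[k] /= n
    H = np.zeros((3, 3))
    for r in range(n):
        for a in range(3):
            for b in range(3):
                H[a, b] += (P[r, a] - pc[a]) * (Q[r, b] - qc[b])
    U, _, Vt = np.linalg.svd(H)
    d = np.linalg.det(np.dot(Vt.T, U.T))
    D = np.eye(3)
    if d < 0.0:
        D[2, 2] = -1.0
    R = np.dot(np.dot(Vt.T, D), U.T)
    return R, pc, qc


@njit(cache=False)
def _tm_refine(A, B, sel0, d0, max_iter):
    """Iterate superpose-on-subset / reselect d < d0 from one seed subset."""
    L = A.shape[0]
    sel = sel0.copy()
    best = 0.0
    d = np.empty(L)
    for _ in range(max_iter):
        nsel = 0
        for i in range(L):
            if sel[i]:
                nsel += 1
        if nsel < 3:
            break
        R, pc, qc = _kabsch(A[sel], B[sel])
        for i in range(L):
            x = A[i, 0] - pc[0]
            y = A[i, 1] - pc[1]
            z = A[i, 2] - pc[2]
            dx = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z + qc[0] - B[i, 0]
            dy = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z + qc[1] - B[i, 1]
            dz = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z + qc[2] - B[i, 2]
            d[i] = np.sqrt(dx * dx + dy * dy + dz * dz)
        tm = 0.0
        for i in range(L):
            tm += 1.0 / (1.0 + (d[i] / d0) ** 2)
        tm /= L
        if tm > best:
            best = tm
        new = d < d0
        nnew = 0
        for i in range(L):
            if new[i]:
                nnew += 1
        if nnew < 3:
            order = np.argsort(d)
            new = np.zeros(L, np.bool_)
            for r in range(3):
                new[order[r]] = True
        same = True
        for i in range(L):
            if new[i] != sel[i]:
                same = False
                break
        if same:
            break
        sel = new
    return best


@njit(cache=False)
def tm_kernel(A, B, d0, stride, max_iter):
    """TM-score under fixed correspondence, maximised over superpositions.

    Seeds the iterative superposition from contiguous fragments of lengths
    {L, L/2, L/4} placed every `stride` residues (plus the chain tail).
    """
    L = A.shape[0]
    best = 0.0
    lens = np.empty(3, np.int64)
    lens[0] = L
    lens[1] = L // 2
    lens[2] = L // 4
    for li in range(3):
        flen = lens[li]
        if flen < 4:
            continue
        start = 0
        done_tail = False
        while start + flen <= L:
            sel = np.zeros(L, np.bool_)
            sel[start:start + flen] = True
            tm = _tm_refine(A, B, sel, d0, max_iter)
            if tm > best:
                best = tm
            if start + flen == L:
                done_tail = True
            start += stride
        if not done_tail:
            start = L - flen
            sel = np.zeros(L, np.bool_)
            sel[start:start + flen] = True
            tm = _tm_refine(A, B, sel, d0, max_iter)
            if tm > best:
                best = tm
    return best
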