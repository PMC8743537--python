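"""Numba dynamic-programming kernels: pairwise alignment and profile-HMM scoring.

All kernels operate on integer-encoded sequences (indices into the 21-letter
alphabet, X last) and log-space parameter arrays in natural-log units.  The
public wrappers in `align` and `hmm` handle encoding and unit conversion.
Score recurrences keep only two rows in memory (the matrices are strongly
memory-bound at RdRP scale); tracebacks use packed per-cell pointers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=True)
def nw_affine(a, b, sub, gap_open, gap_extend):
    """Global (Needleman–Wunsch) alignment with affine gaps.

    A gap of length k costs gap_open + k*gap_extend.  Returns (score, ops)
    where ops lists alignment columns in order: 0 = residue–residue,
    1 = gap in `a` (consumes b), 2 = gap in `b` (consumes a).  Ties prefer
    0 over 1 over 2.
    """
    la, lb = len(a), len(b)
    go = gap_open + gap_extend  # first gapped residue
    ge = gap_extend

    prev_m = np.full(lb + 1, NEG_INF)
    prev_x = np.full(lb + 1, NEG_INF)
    prev_y = np.full(lb + 1, NEG_INF)
    cur_m = np.full(lb + 1, NEG_INF)
    cur_x = np.full(lb + 1, NEG_INF)
    cur_y = np.full(lb + 1, NEG_INF)
    # packed pointers: bits 0-1 into-M, 2-3 into-X, 4-5 into-Y (0=M,1=X,2=Y)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.uint8)

    prev_m[0] = 0.0
    for j in range(1, lb + 1):
        prev_x[j] = -(go + (j - 1) * ge)
        if j > 1:
            ptr[0, j] = 1 << 2
    for i in range(1, la + 1):
        ai = a[i - 1]
        cur_m[0] = NEG_INF
        cur_x[0] = NEG_INF
        cur_y[0] = -(go + (i - 1) * ge)
        ptr[i, 0] = (2 << 4) if i > 1 else 0
        for j in range(1, lb + 1):
            bj = b[j - 1]
            # M: consume both
            s0 = prev_m[j - 1]
            s1 = prev_x[j - 1]
            s2 = prev_y[j - 1]
            pm = 0
            if s1 > s0:
                s0, pm = s1, 1
            if s2 > s0:
                s0, pm = s2, 2
            cur_m[j] = s0 + sub[ai, bj]
            # X: gap in a, consume b
            s0 = cur_m[j - 1] - go
            s1 = cur_x[j - 1] - ge
            s2 = cur_y[j - 1] - go
            px = 0
            if s1 > s0:
                s0, px = s1, 1
            if s2 > s0:
                s0, px = s2, 2
            cur_x[j] = s0
            # Y: gap in b, consume a
            s0 = prev_m[j] - go
            s1 = prev_x[j] - go
            s2 = prev_y[j] - ge
            py = 0
            if s1 > s0:
                s0, py = s1, 1
            if s2 > s0:
                s0, py = s2, 2
            cur_y[j] = s0
            ptr[i, j] = pm | (px << 2) | (py << 4)
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y

    state = 0
    score = prev_m[lb]
    if prev_x[lb] > score:
        score, state = prev_x[lb], 1
    if prev_y[lb] > score:
        score, state = prev_y[lb], 2

    ops = np.empty(la + lb, dtype=np.int8)
    k = la + lb
    i, j = la, lb
    while i > 0 or j > 0:
        k -= 1
        p = ptr[i, j]
        if state == 0:
            ops[k] = 0
            state = p & 3
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = (p >> 2) & 3
            j -= 1
        else:
            ops[k] = 2
            state = (p >> 4) & 3
            i -= 1
    return score, ops[k:]


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Smith–Waterman local alignment score with affine gaps (score only)."""
    la, lb = len(a), len(b)
    go = gap_open + gap_extend
    ge = gap_extend
    prev_h = np.zeros(lb + 1)
    prev_f = np.full(lb + 1, NEG_INF)
    cur_h = np.zeros(lb + 1)
    cur_f = np.full(lb + 1, NEG_INF)
    best = 0.0
    for i in range(1, la + 1):
        ai = a[i - 1]
        cur_h[0] = 0.0
        e = NEG_INF  # gap-in-a state, extends along the row
        for j in range(1, lb + 1):
            e = max(cur_h[j - 1] - go, e - ge)
            f = max(prev_h[j] - go, prev_f[j] - ge)
            h = prev_h[j - 1] + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            cur_h[j] = h
            cur_f[j] = f
            if h > best:
                best = h
        prev_h, cur_h = cur_h, prev_h
        prev_f, cur_f = cur_f, prev_f
    return best


@njit(cache=True)
def hmm_viterbi(x, lm, li, tmm, tmi, tmd, tim, tii, tdm, tdd):
    """Viterbi score (natural log odds) for a local-in-sequence,
    global-in-model Plan7-style profile.

    x: encoded query (length L); lm/li: (M+1, A) log-odds emissions for
    match/insert states (row 0 unused); transition vectors indexed by source
    node in natural log (tmm[0] = B→M1, tmd[0] = B→D1).  Unmatched query
    prefix/suffix residues contribute zero.
    """
    L = len(x)
    M = lm.shape[0] - 1
    pm = np.full(M + 1, NEG_INF)
    pi = np.full(M + 1, NEG_INF)
    pd = np.full(M + 1, NEG_INF)
    cm = np.full(M + 1, NEG_INF)
    ci = np.full(M + 1, NEG_INF)
    cd = np.full(M + 1, NEG_INF)

    # i = 0: all-delete entry
    pd[1] = tmd[0]
    for k in range(2, M + 1):
        pd[k] = pd[k - 1] + tdd[k - 1]
    best = max(pm[M], pd[M])

    for i in range(1, L + 1):
        xi = x[i - 1]
        cm[1] = lm[1, xi] + tmm[0]
        for k in range(2, M + 1):
            v = pm[k - 1] + tmm[k - 1]
            w = pi[k - 1] + tim[k - 1]
            u = pd[k - 1] + tdm[k - 1]
            if w > v:
                v = w
            if u > v:
                v = u
            cm[k] = lm[k, xi] + v
        for k in range(1, M):
            v = pm[k] + tmi[k]
            w = pi[k] + tii[k]
            ci[k] = li[k, xi] + (v if v > w else w)
        cd[1] = tmd[0]
        for k in range(2, M + 1):
            v = cm[k - 1] + tmd[k - 1]
            w = cd[k - 1] + tdd[k - 1]
            cd[k] = v if v > w else w
        if cm[M] > best:
            best = cm[M]
        if cd[M] > best:
            best = cd[M]
        pm, cm = cm, pm
        pi, ci = ci, pi
        pd, cd = cd, pd
    return best


@njit(cache=True)
def hmm_forward(x, lm, li, tmm, tmi, tmd, tim, tii, tdm, tdd):
    """Forward score (natural log odds): logsumexp over all legal paths and
    all free prefix/suffix placements."""
    L = len(x)
    M = lm.shape[0] - 1
    pm = np.full(M + 1, NEG_INF)
    pi = np.full(M + 1, NEG_INF)
    pd = np.full(M + 1, NEG_INF)
    cm = np.full(M + 1, NEG_INF)
    ci = np.full(M + 1, NEG_INF)
    cd = np.full(M + 1, NEG_INF)

    pd[1] = tmd[0]
    for k in range(2, M + 1):
        pd[k] = pd[k - 1] + tdd[k - 1]
    total = np.logaddexp(pm[M], pd[M])

    for i in range(1, L + 1):
        xi = x[i - 1]
        cm[1] = lm[1, xi] + tmm[0]
        for k in range(2, M + 1):
            v = np.logaddexp(pm[k - 1] + tmm[k - 1], pi[k - 1] + tim[k - 1])
            v = np.logaddexp(v, pd[k - 1] + tdm[k - 1])
            cm[k] = lm[k, xi] + v
        for k in range(1, M):
            ci[k] = li[k, xi] + np.logaddexp(pm[k] + tmi[k], pi[k] + tii[k])
        cd[1] = tmd[0]
        for k in range(2, M + 1):
            cd[k] = np.logaddexp(cm[k - 1] + tmd[k - 1], cd[k - 1] + tdd[k - 1])
        total = np.logaddexp(total, cm[M])
        total = np.logaddexp(total, cd[M])
        pm, cm = cm, pm
        pi, ci = ci, pi
        pd, cd = cd, pd
    return total


@njit(cache=True)
def hmm_viterbi_ptr(x, lm, li, tmm, tmi, tmd, tim, tii, tdm, tdd):
    """Viterbi with backpointers for path reconstruction.

    Pointer codes — into M: 0 from M, 1 from I, 2 from D, 3 from B;
    into I: 0 from M, 1 from I; into D: 0 from M, 1 from D, 2 from B.
    Returns (score, end_i, end_state, PM, PI, PD); end_state 0=M, 2=D.
    """
    L = len(x)
    M = lm.shape[0] - 1
    VM = np.full((L + 1, M + 1), NEG_INF)
    VI = np.full((L + 1, M + 1), NEG_INF)
    VD = np.full((L + 1, M + 1), NEG_INF)
    PM = np.zeros((L + 1, M + 1), dtype=np.int8)
    PI = np.zeros((L + 1, M + 1), dtype=np.int8)
    PD = np.zeros((L + 1, M + 1), dtype=np.int8)

    for i in range(0, L + 1):
        if i >= 1:
            xi = x[i - 1]
            VM[i, 1] = lm[1, xi] + tmm[0]
            PM[i, 1] = 3
            for k in range(2, M + 1):
                v, p = VM[i - 1, k - 1] + tmm[k - 1], 0
                w = VI[i - 1, k - 1] + tim[k - 1]
                if w > v:
                    v, p = w, 1
                u = VD[i - 1, k - 1] + tdm[k - 1]
                if u > v:
                    v, p = u, 2
                VM[i, k] = lm[k, xi] + v
                PM[i, k] = p
            for k in range(1, M):
                v, p = VM[i - 1, k] + tmi[k], 0
                w = VI[i - 1, k] + tii[k]
                if w > v:
                    v, p = w, 1
                VI[i, k] = li[k, xi] + v
                PI[i, k] = p
        VD[i, 1] = tmd[0]
        PD[i, 1] = 2
        for k in range(2, M + 1):
            v, p = VM[i, k - 1] + tmd[k - 1], 0
            w = VD[i, k - 1] + tdd[k - 1]
            if w > v:
                v, p = w, 1
            VD[i, k] = v
            PD[i, k] = p

    best = NEG_INF
    end_i = 0
    end_state = 0
    for i in range(0, L + 1):
        if VM[i, M] > best:
            best, end_i, end_state = VM[i, M], i, 0
        if VD[i, M] > best:
            best, end_i, end_state = VD[i, M], i, 2
    return best, end_i, end_state, PM, PI, PD
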