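"""Dynamic-programming kernels for glocal profile alignment.

Both kernels run over natural-log parameter arrays prepared by
:mod:`famscan.scoring`.  When numba is importable the kernels are JIT
compiled; otherwise the identical pure-Python code runs (slow, but only
exercised on tiny inputs).

Path set scored (see :mod:`famscan.profile` for the architecture): a
left flank of background-emitted residues, entry into match column 1,
any match/insert/delete path that reaches match column M, then a right
flank.  A sequence/profile pair with no feasible path scores ``-inf``.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


NEG_INF = -math.inf


@njit(cache=True)
def _lse2(a, b):
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def viterbi_ln(obs, lem, lt, lb, ln_eta, ln_leave):
    """Best-path ln-probability and 1-based envelope.

    Returns ``(ln_p, start, end)``; ``ln_p = -inf`` (with zero envelope)
    when no path exists.
    """
    L = obs.shape[0]
    M = lem.shape[0]

    sfx = np.zeros(L + 1)
    for i in range(L - 1, -1, -1):
        sfx[i] = sfx[i + 1] + lb[obs[i]]

    vM = np.full(M, NEG_INF)
    vI = np.full(M, NEG_INF)
    vD = np.full(M, NEG_INF)
    sMv = np.zeros(M, np.int64)
    sIv = np.zeros(M, np.int64)
    sDv = np.zeros(M, np.int64)
    nM = np.full(M, NEG_INF)
    nI = np.full(M, NEG_INF)
    nD = np.full(M, NEG_INF)
    nsM = np.zeros(M, np.int64)
    nsI = np.zeros(M, np.int64)
    nsD = np.zeros(M, np.int64)

    best = NEG_INF
    best_s = 0
    best_e = 0
    flank = 0.0  # ln prob of emitting residues 1..i-1 in the left flank

    for i in range(1, L + 1):
        x = obs[i - 1]
        # match states
        nM[0] = lem[0, x] + flank + ln_leave
        nsM[0] = i
        for k in range(1, M):
            bm = vM[k - 1] + lt[k - 1, 0]
            bi = vI[k - 1] + lt[k - 1, 3]
            bd = vD[k - 1] + lt[k - 1, 5]
            if bm >= bi and bm >= bd:
                nM[k] = lem[k, x] + bm
                nsM[k] = sMv[k - 1]
            elif bi >= bd:
                nM[k] = lem[k, x] + bi
                nsM[k] = sIv[k - 1]
            else:
                nM[k] = lem[k, x] + bd
                nsM[k] = sDv[k - 1]
        # delete states (no emission; depend on current-position match values)
        nD[0] = NEG_INF
        for k in range(1, M):
            dm = nM[k - 1] + lt[k - 1, 2]
            dd = nD[k - 1] + lt[k - 1, 6]
            if dm >= dd:
                nD[k] = dm
                nsD[k] = nsM[k - 1]
            else:
                nD[k] = dd
                nsD[k] = nsD[k - 1]
        # insert states (I_M does not exist)
        for k in range(M - 1):
            im = vM[k] + lt[k, 1]
            ii = vI[k] + lt[k, 4]
            if im >= ii:
                nI[k] = lb[x] + im
                nsI[k] = sMv[k]
            else:
                nI[k] = lb[x] + ii
                nsI[k] = sIv[k]
        if M > 1:
            nI[M - 1] = NEG_INF

        tot = nM[M - 1] + (L - i) * ln_eta + sfx[i] + ln_leave
        if tot > best:
            best = tot
            best_s = nsM[M - 1]
            best_e = i

        vM, nM = nM, vM
        vI, nI = nI, vI
        vD, nD = nD, vD
        sMv, nsM = nsM, sMv
        sIv, nsI = nsI, sIv
        sDv, nsD = nsD, sDv
        flank += ln_eta + lb[x]

    return best, best_s, best_e


@njit(cache=True)
def forward_ln(obs, lem, lt, lb, ln_eta, ln_leave):
    """ln of the summed probability over all glocal paths."""
    L = obs.shape[0]
    M = lem.shape[0]

    sfx = np.zeros(L + 1)
    for i in range(L - 1, -1, -1):
        sfx[i] = sfx[i + 1] + lb[obs[i]]

    vM = np.full(M, NEG_INF)
    vI = np.full(M, NEG_INF)
    vD = np.full(M, NEG_INF)
    nM = np.full(M, NEG_INF)
    nI = np.full(M, NEG_INF)
    nD = np.full(M, NEG_INF)

    total = NEG_INF
    flank = 0.0

    for i in range(1, L + 1):
        x = obs[i - 1]
        nM[0] = lem[0, x] + flank + ln_leave
        for k in range(1, M):
            acc = _lse2(vM[k - 1] + lt[k - 1, 0], vI[k - 1] + lt[k - 1, 3])
            acc = _lse2(acc, vD[k - 1] + lt[k - 1, 5])
            nM[k] = lem[k, x] + acc
        nD[0] = NEG_INF
        for k in range(1, M):
            nD[k] = _lse2(nM[k - 1] + lt[k - 1, 2], nD[k - 1] + lt[k - 1, 6])
        for k in range(M - 1):
            nI[k] = lb[x] + _lse2(vM[k] + lt[k, 1], vI[k] + lt[k, 4])
        if M > 1:
            nI[M - 1] = NEG_INF

        total = _lse2(total, nM[M - 1] + (L - i) * ln_eta + sfx[i] + ln_leave)

        vM, nM = nM, vM
        vI, nI = nI, vI
        vD, nD = nD, vD
        flank += ln_eta + lb[x]

    return total
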