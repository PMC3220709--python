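"""Independent brute-force oracles used by the test suite.

The path enumerator below recomputes glocal scores by explicit
depth-first enumeration of every state path, sharing nothing with the
dynamic-programming kernels it checks.
"""

from __future__ import annotations

import math

import numpy as np

from famscan.msa import AA_INDEX

LN2 = math.log(2.0)


def enumerate_glocal_paths(profile, seq: str) -> list[tuple[float, int, int]]:
    """All (probability, start, end) glocal paths of ``seq`` through ``profile``.

    Architecture mirrored independently: left background flank, entry at
    match column 1, match/insert/delete moves, exit at match column M,
    right background flank.
    """
    obs = [AA_INDEX[c] for c in seq]
    L = len(obs)
    M = profile.n_match
    em = profile.match_emissions
    bg = profile.background
    ins = profile.insert_emissions
    t = profile.transitions
    eta = profile.flank_loop
    leave = 1.0 - eta

    out: list[tuple[float, int, int]] = []

    def finish(prob: float, s: int, e: int) -> None:
        tail = prob * leave
        for j in range(e, L):
            tail *= eta * bg[obs[j]]
        out.append((tail, s, e))

    def from_match(k: int, i: int, prob: float, s: int) -> None:
        # arrived at match column k (1-based) having just emitted obs[i-1]
        if k == M:
            finish(prob, s, i)
            return
        if i < L:
            from_match(k + 1, i + 1, prob * t[k - 1, 0] * em[k][obs[i]], s)
            from_insert(k, i + 1, prob * t[k - 1, 1] * ins[obs[i]], s)
        from_delete(k + 1, i, prob * t[k - 1, 2], s)

    def from_insert(k: int, i: int, prob: float, s: int) -> None:
        if i < L:
            from_match(k + 1, i + 1, prob * t[k - 1, 3] * em[k][obs[i]], s)
            from_insert(k, i + 1, prob * t[k - 1, 4] * ins[obs[i]], s)

    def from_delete(k: int, i: int, prob: float, s: int) -> None:
        if k == M:
            return  # exit is only through match column M
        if i < L:
            from_match(k + 1, i + 1, prob * t[k - 1, 5] * em[k][obs[i]], s)
        from_delete(k + 1, i, prob * t[k - 1, 6], s)

    for s in range(1, L + 1):
        pref = leave
        for j in range(s - 1):
            pref *= eta * bg[obs[j]]
        from_match(1, s, pref * em[0][obs[s - 1]], s)

    return out


def null_probability(profile, seq: str) -> float:
    obs = [AA_INDEX[c] for c in seq]
    eta = profile.flank_loop
    p = 1.0 - eta
    for x in obs:
        p *= eta * profile.background[x]
    return p


def oracle_forward_bits(profile, seq: str) -> float:
    paths = enumerate_glocal_paths(profile, seq)
    total = sum(p for p, _, _ in paths)
    if total == 0:
        return float("-inf")
    return math.log2(total / null_probability(profile, seq))


def oracle_viterbi_bits(profile, seq: str) -> tuple[float, tuple[int, int]]:
    paths = enumerate_glocal_paths(profile, seq)
    if not paths:
        return float("-inf"), (0, 0)
    best, s, e = max(paths, key=lambda x: x[0])
    if best == 0:
        return float("-inf"), (0, 0)
    return math.log2(best / null_probability(profile, seq)), (s, e)


def least_squares_topology(labels, dmat) -> frozenset:
    """Best unrooted 4-taxon split by least-squares fit of branch lengths.

    Brute force over the three topologies; returns the winning pair
    grouping as a frozenset of two labels.
    """
    a, b, c, d = range(4)
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    best = None
    for (i, j), (k, l) in pairings:
        # five branch lengths x solve min ||Ax - d||
        A = np.zeros((6, 5))
        y = np.zeros(6)
        pairs = [(i, j), (i, k), (i, l), (j, k), (j, l), (k, l)]
        ext = {i: 0, j: 1, k: 2, l: 3}
        for row, (u, v) in enumerate(pairs):
            A[row, ext[u]] = 1
            A[row, ext[v]] = 1
            same_side = {u, v} in ({i, j}, {k, l})
            if not same_side:
                A[row, 4] = 1
            y[row] = dmat[u, v]
        x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ x - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, frozenset({labels[i], labels[j]}))
    return best[1]
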