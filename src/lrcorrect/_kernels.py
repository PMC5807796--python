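"""Numba-compiled rank / backward-search kernels.

Two kernel families, one per FM-index backend:

* ``*_bits`` — packed 64-bit occupancy words per symbol plus exclusive
  prefix popcounts (the fast, memory-hungry default).
* ``*_sampled`` — occurrence checkpoints every ``rate`` symbols plus a
  linear scan of the decoded BWT inside the block (slower, smaller).

Both expose the same three operations: a scalar ``rank``, a batched
backward-search pattern counter and a per-window counter used for read
classification.  The pure-Python layer keeps the two backends behind one
class interface; tests assert they answer every query identically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_U1 = np.uint64(1)
_U2 = np.uint64(2)
_U4 = np.uint64(4)
_U56 = np.uint64(56)


@njit(cache=True)
def _popcount64(x):
    x = x - ((x >> _U1) & _M1)
    x = (x & _M2) + ((x >> _U2) & _M2)
    x = (x + (x >> _U4)) & _M4
    return np.int64((x * _H01) >> _U56)


@njit(cache=True)
def rank_bits(words, prefix, c, p):
    """Occurrences of symbol ``c`` in BWT[0:p] (bit-array backend)."""
    w = p >> 6
    r = prefix[c, w]
    b = np.uint64(p & 63)
    if b:
        mask = (_U1 << b) - _U1
        r += _popcount64(words[c, w] & mask)
    return r


@njit(cache=True)
def count_patterns_bits(words, prefix, offsets, total, pats, out):
    """Backward-search count for each row of ``pats`` (single strand)."""
    m, k = pats.shape
    for i in range(m):
        lo = np.int64(0)
        hi = total
        for j in range(k - 1, -1, -1):
            c = pats[i, j]
            lo = offsets[c] + rank_bits(words, prefix, c, lo)
            hi = offsets[c] + rank_bits(words, prefix, c, hi)
            if lo >= hi:
                break
        out[i] = hi - lo if hi > lo else 0


@njit(cache=True)
def window_counts_bits(words, prefix, offsets, total, codes, k, out):
    """Count every length-``k`` window of ``codes`` (single strand)."""
    m = codes.size - k + 1
    for i in range(m):
        lo = np.int64(0)
        hi = total
        for j in range(k - 1, -1, -1):
            c = codes[i + j]
            lo = offsets[c] + rank_bits(words, prefix, c, lo)
            hi = offsets[c] + rank_bits(words, prefix, c, hi)
            if lo >= hi:
                break
        out[i] = hi - lo if hi > lo else 0


@njit(cache=True)
def locus_dp(t, r, status):
    """Global unit-cost alignment of read ``r`` to template ``t`` with
    traceback; marks ``status[i]`` True where template locus ``i`` aligns to
    an identical read base.  Tie order: diagonal, template gap, read gap."""
    n = t.size
    m = r.size
    D = np.empty((n + 1, m + 1), np.int32)
    for j in range(m + 1):
        D[0, j] = j
    for i in range(1, n + 1):
        D[i, 0] = i
        ti = t[i - 1]
        for j in range(1, m + 1):
            best = D[i - 1, j - 1] + (0 if r[j - 1] == ti else 1)
            up = D[i - 1, j] + 1
            if up < best:
                best = up
            left = D[i, j - 1] + 1
            if left < best:
                best = left
            D[i, j] = best
    i = n
    j = m
    while i > 0 and j > 0:
        here = D[i, j]
        cost = 0 if t[i - 1] == r[j - 1] else 1
        if here == D[i - 1, j - 1] + cost:
            status[i - 1] = cost == 0
            i -= 1
            j -= 1
        elif here == D[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1


@njit(cache=True)
def rank_sampled(bwt, checkpoints, rate, c, p):
    """Occurrences of symbol ``c`` in BWT[0:p] (sampled backend)."""
    j = p // rate
    r = checkpoints[c, j]
    for i in range(j * rate, p):
        if bwt[i] == c:
            r += 1
    return r


@njit(cache=True)
def count_patterns_sampled(bwt, checkpoints, rate, offsets, total, pats, out):
    m, k = pats.shape
    for i in range(m):
        lo = np.int64(0)
        hi = total
        for j in range(k - 1, -1, -1):
            c = pats[i, j]
            lo = offsets[c] + rank_sampled(bwt, checkpoints, rate, c, lo)
            hi = offsets[c] + rank_sampled(bwt, checkpoints, rate, c, hi)
            if lo >= hi:
                break
        out[i] = hi - lo if hi > lo else 0


@njit(cache=True)
def window_counts_sampled(bwt, checkpoints, rate, offsets, total, codes, k, out):
    m = codes.size - k + 1
    for i in range(m):
        lo = np.int64(0)
        hi = total
        for j in range(k - 1, -1, -1):
            c = codes[i + j]
            lo = offsets[c] + rank_sampled(bwt, checkpoints, rate, c, lo)
            hi = offsets[c] + rank_sampled(bwt, checkpoints, rate, c, hi)
            if lo >= hi:
                break
        out[i] = hi - lo if hi > lo else 0
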