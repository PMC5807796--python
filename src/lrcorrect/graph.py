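"""Implicit de Bruijn graph traversal over the FM-index.

A k-mer is a node iff its (forward + reverse-complement) frequency reaches
the threshold ``t`` in force — the graph is "pruned" at query time, never
materialised.  Two depth-first searches repair weak regions:

* :func:`bridge` — connect a seed k-mer to a target k-mer (internal weak
  region flanked by solid sequence on both sides);
* :func:`extend` — extend from a seed towards a read end (head/tail weak
  region with a single solid flank).

Both are exhaustive depth-first searches in A<C<G<T edge order, bounded by
a branch budget ``L``: every expansion at which two or more qualifying
successors exist spends one unit, and exceeding the budget aborts the whole
traversal, returning whatever complete paths were already found.  At most
``MAX_PATHS`` complete paths are retained per traversal (first found in the
deterministic order).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._codec import decode, encode, revcomp_codes
from .fmindex import FmIndex

__all__ = [
    "TraversalLimits",
    "CandidatePath",
    "MAX_PATHS",
    "is_solid",
    "bridge",
    "extend",
]

#: complete paths retained per traversal (first found, deterministic order)
MAX_PATHS = 10

_BASE_CODE_LIST = (1, 2, 3, 5)  # A, C, G, T


@dataclass(frozen=True)
class TraversalLimits:
    """Branch budget and path-length bounds (in bases, seed included)."""

    branch_limit: int
    min_length: int
    max_length: int

    def __post_init__(self):
        if self.branch_limit < 1:
            raise ValueError("branch_limit must be >= 1")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


@dataclass(frozen=True)
class CandidatePath:
    """A complete traversal result, seed k-mer included at the start."""

    sequence: str
    min_interior_frequency: int


def is_solid(fm: FmIndex, kmer, t: int) -> bool:
    """Solid iff total frequency >= t (strictly below t is weak)."""
    if t < 1:
        raise ValueError("threshold t must be >= 1")
    return fm.count_kmer(kmer) >= t


def _dfs(
    fm: FmIndex,
    seed: np.ndarray,
    target: Optional[np.ndarray],
    k: int,
    limits: TraversalLimits,
    t: int,
):
    """Core DFS; returns a list of (codes-bytes, min_frequency) tuples.

    With a ``target`` this is a bridge search: a branch is recorded and
    stopped the first time the path ends with the target inside the length
    bounds; paths that hit ``max_length`` without the target die.  Without a
    target it is an extension: paths are recorded when they die or reach
    ``max_length``, and kept if at least ``min_length`` long.
    """
    seed_count = fm.count_codes(seed)
    if seed_count < t:
        return []
    minl, maxl = limits.min_length, limits.max_length
    target_b = None if target is None else bytes(np.asarray(target, np.uint8))
    path = bytearray(np.asarray(seed, np.uint8).tobytes())
    minf = [seed_count]
    found: List[tuple] = []
    branches_used = 0

    # root terminal conditions
    if target_b is not None:
        if minl <= len(path) <= maxl and bytes(path[-k:]) == target_b:
            return [(bytes(path), seed_count)]
        if len(path) >= maxl:
            return []
    elif len(path) >= maxl:
        return [(bytes(path), seed_count)] if len(path) >= minl else []

    def successors():
        context = np.frombuffer(bytes(path[-(k - 1):]) if k > 1 else b"", np.uint8)
        freqs = fm.count_extensions(context, k)
        return [
            (_BASE_CODE_LIST[i], int(freqs[i]))
            for i in range(4)
            if freqs[i] >= t
        ]

    succ = successors()
    if not succ:
        if target_b is None and len(path) >= minl:
            return [(bytes(path), seed_count)]
        return []
    if len(succ) >= 2:
        branches_used += 1
        if branches_used > limits.branch_limit:
            return found
    frames = [[succ, 0]]

    while frames:
        top = frames[-1]
        if top[1] >= len(top[0]):
            frames.pop()
            if frames:
                path.pop()
                minf.pop()
            continue
        base, freq = top[0][top[1]]
        top[1] += 1
        path.append(base)
        minf.append(min(minf[-1], freq))
        n = len(path)

        if target_b is not None and n >= minl and bytes(path[-k:]) == target_b:
            found.append((bytes(path), minf[-1]))
            if len(found) >= MAX_PATHS:
                return found
            path.pop(); minf.pop()
            continue
        if n >= maxl:
            if target_b is None and n >= minl:
                found.append((bytes(path), minf[-1]))
                if len(found) >= MAX_PATHS:
                    return found
            path.pop(); minf.pop()
            continue

        succ = successors()
        if not succ:
            if target_b is None and n >= minl:
                found.append((bytes(path), minf[-1]))
                if len(found) >= MAX_PATHS:
                    return found
            path.pop(); minf.pop()
            continue
        if len(succ) >= 2:
            branches_used += 1
            if branches_used > limits.branch_limit:
                return found
        frames.append([succ, 0])

    return found


def _to_candidates(raw, reverse_complement: bool = False) -> List[CandidatePath]:
    out = []
    for seq_bytes, mf in raw:
        codes = np.frombuffer(seq_bytes, np.uint8)
        if reverse_complement:
            codes = revcomp_codes(codes)
        out.append(CandidatePath(decode(codes), mf))
    return out


def bridge(
    fm: FmIndex,
    seed_kmer: str,
    target_kmer: str,
    k: int,
    limits: TraversalLimits,
    t: int,
) -> List[CandidatePath]:
    """All paths (up to the limits) from ``seed_kmer`` that end with
    ``target_kmer`` within the length bounds, in depth-first A<C<G<T order.

    If the forward traversal yields nothing, the search is retried from the
    reverse complement of the target towards the reverse complement of the
    seed (branching may be cheaper from that side) and any results are
    reverse-complemented back.
    """
    seed = encode(seed_kmer)
    target = encode(target_kmer)
    if seed.size != k or target.size != k:
        raise ValueError("seed and target must both have length k")
    raw = _dfs(fm, seed, target, k, limits, t)
    if raw:
        return _to_candidates(raw)
    raw = _dfs(fm, revcomp_codes(target), revcomp_codes(seed), k, limits, t)
    return _to_candidates(raw, reverse_complement=True)


def extend(
    fm: FmIndex,
    seed_kmer: str,
    k: int,
    limits: TraversalLimits,
    t: int,
    direction: str = "tail",
) -> List[CandidatePath]:
    """Extension paths from ``seed_kmer`` towards a read end.

    ``tail`` extends rightwards; ``head`` extends leftwards, implemented as
    a rightward traversal on the reverse complement, so returned head paths
    *end* with the seed k-mer.
    """
    if direction not in ("head", "tail"):
        raise ValueError("direction must be 'head' or 'tail'")
    seed = encode(seed_kmer)
    if seed.size != k:
        raise ValueError("seed must have length k")
    if direction == "head":
        raw = _dfs(fm, revcomp_codes(seed), None, k, limits, t)
        return _to_candidates(raw, reverse_complement=True)
    raw = _dfs(fm, seed, None, k, limits, t)
    return _to_candidates(raw)
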