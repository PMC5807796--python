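"""Two-pass long-read correction driver.

Each pass over a read is identical machinery at a different k-mer size:

1. query the frequency of every k-mer in the read (forward + reverse
   complement summed);
2. derive the per-read solidity threshold ``t = max(T, ceil(F * m))`` where
   ``m`` is the median of frequencies at or above the absolute floor ``T``;
3. merge consecutive weak / solid k-mer positions into regions;
4. repair each weak region left to right — bridge between the closest solid
   anchors when two flanks exist, extend from the single anchor for head or
   tail regions, leave flankless (all-weak) reads untouched;
5. among returned candidate paths, the one with the smallest edit distance
   to the original segment replaces it (ties: higher minimum interior
   frequency, then lexicographic).

The short-k pass fixes most sequencing errors; the long-K pass re-runs the
same procedure where longer anchors disambiguate repeats the short pass
could not bridge.  The branch budget scales with the pass, ``L = B * k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._align import levenshtein, prefix_levenshtein
from ._codec import encode
from .fmindex import FmIndex
from .graph import CandidatePath, TraversalLimits, bridge, extend

__all__ = [
    "CorrectionParams",
    "ReadRegion",
    "dynamic_threshold",
    "classify_and_segment",
    "repair_region",
    "correct_pass",
    "correct_read",
    "correct_reads",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Correction parameters; the defaults are the published tool defaults.

    ``K`` of ``None`` (or 0) disables the second pass.  ``strict_median``
    switches the median list from frequencies ``>= T`` (default) to
    strictly ``> T``.
    """

    k: int = 21
    K: Optional[int] = 59
    T: int = 5
    F: float = 0.10
    B: int = 4
    strict_median: bool = False

    def __post_init__(self):
        if self.K == 0:
            object.__setattr__(self, "K", None)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.K is not None and self.K <= self.k:
            raise ValueError("K must be greater than k (or absent)")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @property
    def pass_sizes(self) -> Tuple[int, ...]:
        return (self.k,) if self.K is None else (self.k, self.K)


@dataclass(frozen=True)
class ReadRegion:
    """A maximal run of weak or solid k-mer positions (half-open)."""

    kind: str  # "weak" | "solid"
    start: int
    end: int


def dynamic_threshold(
    frequencies, T: int = 5, F: float = 0.10, strict: bool = False
) -> int:
    """Per-read solidity threshold ``t = max(T, ceil(F * m))``.

    ``m`` is the median of the frequencies at/above the absolute floor ``T``
    (strictly above with ``strict=True``); ``m = 0`` when that set is empty,
    in which case ``t = T``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    freqs = np.asarray(frequencies, dtype=np.int64)
    solid = freqs[freqs > T] if strict else freqs[freqs >= T]
    m = float(np.median(solid)) if solid.size else 0.0
    return max(T, math.ceil(F * m))


def _segment(solid_mask: np.ndarray) -> List[ReadRegion]:
    if solid_mask.size == 0:
        return []
    change = np.flatnonzero(solid_mask[1:] != solid_mask[:-1]) + 1
    bounds = np.r_[0, change, solid_mask.size]
    return [
        ReadRegion("solid" if solid_mask[s] else "weak", int(s), int(e))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


def classify_and_segment(read: str, k: int, fm: FmIndex, t: int) -> List[ReadRegion]:
    """Classify every k-mer of ``read`` as weak/solid at threshold ``t`` and
    merge maximal runs into regions.  A read shorter than k yields no
    regions (and passes through correction unchanged)."""
    if len(read) < k:
        return []
    counts = fm.window_counts(encode(read), k)
    return _segment(counts >= t)


def _choose_candidate(
    candidates: Sequence[CandidatePath],
    original: str,
    trim: Optional[str] = None,
    k: int = 0,
) -> Optional[str]:
    """Pick the replacement: smallest edit distance to ``original``, ties by
    larger min interior frequency then lexicographic sequence.

    ``trim`` of ``'tail'``/``'head'`` scores candidates under free-end edit
    distance and trims the winner at its best-scoring end (keeping at least
    the seed k-mer), so extension paths never pad a read arbitrarily.
    """
    if not candidates:
        return None
    scored = []
    for cand in candidates:
        seq = cand.sequence
        if trim == "tail":
            dist, j = prefix_levenshtein(original, seq, min_prefix=k)
            seq = seq[:j]
        elif trim == "head":
            dist, j = prefix_levenshtein(original[::-1], seq[::-1], min_prefix=k)
            seq = seq[len(seq) - j :]
        else:
            dist = levenshtein(original, seq)
        scored.append((dist, -cand.min_interior_frequency, seq))
    scored.sort()
    return scored[0][2]


def repair_region(
    read: str,
    region: ReadRegion,
    flanks: Tuple[Optional[ReadRegion], Optional[ReadRegion]],
    fm: FmIndex,
    k: int,
    t: int,
    L: int,
) -> Optional[Tuple[int, int, str]]:
    """Propose a repair for one weak region of ``read``.

    ``flanks`` holds the neighbouring solid regions (left, right), either of
    which may be None.  Returns ``(start, end, replacement)`` in base
    coordinates — the span runs from the start of the seed k-mer to the end
    of the target k-mer — or None when no change should be made (no flanks,
    no candidate path, or the best candidate already equals the original).
    """
    if region.kind != "weak":
        raise ValueError("repair_region expects a weak region")
    left, right = flanks
    if left is None and right is None:
        return None

    if left is not None and right is not None:
        seed_pos = region.start - 1
        target_pos = region.end
        a, b = seed_pos, target_pos + k
        original = read[a:b]
        limits = TraversalLimits(
            L, max(k, len(original) // 2), math.ceil(1.5 * len(original)) + k
        )
        cands = bridge(
            fm, read[seed_pos : seed_pos + k], read[target_pos : target_pos + k],
            k, limits, t,
        )
        best = _choose_candidate(cands, original)
    elif right is not None:  # weak head: extend leftwards from first solid k-mer
        seed_pos = region.end
        a, b = 0, seed_pos + k
        original = read[a:b]
        limits = TraversalLimits(
            L, max(k, len(original) // 2), math.ceil(1.5 * len(original)) + k
        )
        cands = extend(fm, read[seed_pos : seed_pos + k], k, limits, t, "head")
        best = _choose_candidate(cands, original, trim="head", k=k)
    else:  # weak tail: extend rightwards from last solid k-mer
        seed_pos = region.start - 1
        a, b = seed_pos, len(read)
        original = read[a:b]
        limits = TraversalLimits(
            L, max(k, len(original) // 2), math.ceil(1.5 * len(original)) + k
        )
        cands = extend(fm, read[seed_pos : seed_pos + k], k, limits, t, "tail")
        best = _choose_candidate(cands, original, trim="tail", k=k)

    if best is None or best == original:
        return None
    return a, b, best


def correct_pass(read: str, k: int, params: CorrectionParams, fm: FmIndex) -> str:
    """One correction pass at k-mer size ``k`` (see module docs)."""
    if len(read) < k:
        return read
    counts = fm.window_counts(encode(read), k)
    t = dynamic_threshold(counts, params.T, params.F, params.strict_median)
    L = params.B * k
    regions = _segment(counts >= t)
    if len(regions) == 1 and regions[0].kind == "weak":
        return read  # no solid start points anywhere
    out = read
    delta = 0
    for i, region in enumerate(regions):
        if region.kind != "weak":
            continue
        left = regions[i - 1] if i > 0 else None
        right = regions[i + 1] if i + 1 < len(regions) else None
        shifted = ReadRegion(region.kind, region.start + delta, region.end + delta)
        shifted_left = (
            None if left is None
            else ReadRegion(left.kind, left.start + delta, left.end + delta)
        )
        shifted_right = (
            None if right is None
            else ReadRegion(right.kind, right.start + delta, right.end + delta)
        )
        result = repair_region(
            out, shifted, (shifted_left, shifted_right), fm, k, t, L
        )
        if result is None:
            continue
        a, b, replacement = result
        out = out[:a] + replacement + out[b:]
        delta += len(replacement) - (b - a)
    return out


def correct_read(read: str, params: CorrectionParams, fm: FmIndex) -> str:
    """Full correction: a short-k pass, then (when configured) a long-K pass
    on the intermediate result; thresholds and the branch budget are
    recomputed for each pass."""
    out = read
    for k in params.pass_sizes:
        out = correct_pass(out, k, params, fm)
    return out


# -- multi-read driver (order-preserving, observationally sequential) --------

_WORKER_STATE: dict = {}


def _init_worker(fm, params):
    _WORKER_STATE["fm"] = fm
    _WORKER_STATE["params"] = params


def _run_worker(read):
    return correct_read(read, _WORKER_STATE["params"], _WORKER_STATE["fm"])


def correct_reads(
    reads: Sequence[str],
    params: CorrectionParams,
    fm: FmIndex,
    processes: int = 1,
) -> List[str]:
    """Correct a read collection, preserving order.

    Reads are corrected independently, so any worker count yields output
    byte-identical to the sequential run.
    """
    reads = list(reads)
    if processes <= 1 or len(reads) < 2:
        return [correct_read(r, params, fm) for r in reads]
    import multiprocessing

    ctx = multiprocessing.get_context("fork")
    chunk = max(1, len(reads) // (processes * 4))
    with ctx.Pool(processes, initializer=_init_worker, initargs=(fm, params)) as pool:
        return pool.map(_run_worker, reads, chunksize=chunk)
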