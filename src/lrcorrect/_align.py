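"""Edit-distance and alignment primitives (unit costs, numpy row DP).

Three entry points:

* :func:`levenshtein` — plain global edit distance, used to pick among
  candidate replacement paths.
* :func:`prefix_levenshtein` — distance from a segment to the best *prefix*
  of a candidate (free right end), used to trim seed-and-extend results.
* :func:`locus_status` — global alignment with traceback, reporting for
  every template position whether the read reproduces it exactly.  This is
  the per-locus "correct / incorrect" call behind the evaluation
  statistics: a template nucleotide is correct iff it is aligned to a
  single, matching read nucleotide; mismatched or deleted template
  positions are incorrect, and read insertions carry no template locus.

The row recurrence vectorises the in-row (leftward, gap-in-template)
dependency with the classic running-minimum trick:
``row[j] = min_{j' <= j} (base[j'] + (j - j'))``.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from . import _kernels
from ._codec import encode


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.int16)
    return encode(seq).astype(np.int16)


def _dp_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Final DP row: distances lev(a, b[:j]) for every j."""
    m = b.size
    ar = np.arange(m + 1, dtype=np.int32)
    row = ar.copy()
    for i in range(1, a.size + 1):
        diag = row[:-1] + (b != a[i - 1])
        up = row[1:] + 1
        base = np.empty(m + 1, np.int32)
        base[0] = i
        base[1:] = np.minimum(diag, up)
        row = np.minimum.accumulate(base - ar) + ar
    return row


def levenshtein(a, b) -> int:
    """Unit-cost edit distance between two sequences (str or code arrays)."""
    a = _as_codes(a)
    b = _as_codes(b)
    if a.size == 0:
        return int(b.size)
    if b.size == 0:
        return int(a.size)
    return int(_dp_rows(a, b)[-1])


def prefix_levenshtein(a, b, min_prefix: int = 0) -> Tuple[int, int]:
    """Best edit distance of ``a`` against any prefix ``b[:j]``, j >= min_prefix.

    Returns ``(distance, j)``.  Ties prefer the prefix length closest to
    ``len(a)`` and then the shorter prefix, so an exact copy of ``a``
    inside ``b`` is always recovered verbatim.
    """
    a = _as_codes(a)
    b = _as_codes(b)
    min_prefix = min(min_prefix, b.size)
    if a.size == 0:
        return min_prefix, min_prefix
    row = _dp_rows(a, b)[min_prefix:]
    best = int(row.min())
    js = np.flatnonzero(row == best) + min_prefix
    j = int(js[np.lexsort((js, np.abs(js - a.size)))[0]])
    return best, j


def locus_status(template, read) -> np.ndarray:
    """Per-template-locus correctness under a global unit-cost alignment.

    Returns a boolean array of ``len(template)``: True where the template
    nucleotide aligns to an identical read nucleotide.  Traceback ties are
    broken deterministically (diagonal, then template gap, then read gap).
    An empty read leaves every locus incorrect.
    """
    t = _as_codes(template)
    r = _as_codes(read)
    status = np.zeros(t.size, dtype=bool)
    if t.size == 0 or r.size == 0:
        return status
    _kernels.locus_dp(t, r, status)
    # template positions never reached by the traceback are deletions and
    # stay incorrect
    return status
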