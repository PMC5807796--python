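"""Shared sequence <-> integer-code plumbing.

The index alphabet is the six symbols ``$ A C G N T`` mapped to codes 0-5
in that (sorted) order.  ``$`` never occurs in a query; ``N`` is a real,
countable symbol but is never proposed by graph traversal.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "$ACGNT"
ALPHABET_SIZE = 6

#: codes of the four proposable nucleotides, in A<C<G<T order
BASE_CODES = np.array([1, 2, 3, 5], dtype=np.uint8)

#: code -> complement code ($ and N are self-complementary)
COMP = np.array([0, 5, 3, 2, 4, 1], dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE_BYTES = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes, uppercasing on the fly.

    Raises ``ValueError`` naming the first offending character if the
    sequence contains anything outside ``{A, C, G, N, T}`` (``$`` is also
    rejected: it is an internal terminator, not a query symbol).
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[raw]
    bad = (codes == 255) | (codes == 0)
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(
            f"illegal character {seq[pos]!r} at position {pos}; "
            "expected one of A, C, G, N, T"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (also decodes ``$`` for BWT debugging)."""
    return _DECODE_BYTES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP[np.asarray(codes, dtype=np.uint8)][::-1].copy()


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
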