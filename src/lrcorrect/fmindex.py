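"""Multi-string BWT construction, run-length serialization and FM-index queries.

The index is built over the short-read set: every read gets its own ``$``
terminator, terminators sort before all bases and ties between terminators
are broken by read index, which makes construction deterministic.  The
resulting FM-index answers exact k-mer frequency queries for *any* k in
O(k) rank steps, which is what lets one structure stand in for every
de Bruijn graph of the read set at once.

Every public k-mer count is the sum of the forward and reverse-complement
occurrences — short reads are sequenced from both strands, so a genomic
k-mer is only meaningfully supported by the two strands together.
Reverse-complement palindromes therefore count double; downstream
thresholds absorb the doubling uniformly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._codec import (
    ALPHABET,
    ALPHABET_SIZE,
    BASE_CODES,
    decode,
    encode,
    revcomp_codes,
)

__all__ = [
    "RleBwt",
    "KmerQuery",
    "FmIndex",
    "BitArrayFmIndex",
    "SampledFmIndex",
    "build_msbwt",
    "build_fm_index",
    "save_rle",
    "load_rle",
]


# ---------------------------------------------------------------------------
# run-length encoded BWT container
# ---------------------------------------------------------------------------

class RleBwt:
    """Run-length encoded multi-string BWT over the alphabet ``$ACGNT``.

    Runs are canonical: lengths are positive and adjacent runs carry
    different symbols.  ``total_counts[0]`` equals the number of indexed
    strings (one terminator each).
    """

    __slots__ = ("run_symbols", "run_lengths", "total_counts")

    def __init__(self, run_symbols: np.ndarray, run_lengths: np.ndarray):
        run_symbols = np.asarray(run_symbols, dtype=np.uint8)
        run_lengths = np.asarray(run_lengths, dtype=np.int64)
        if run_symbols.shape != run_lengths.shape or run_symbols.ndim != 1:
            raise ValueError("run_symbols and run_lengths must be 1-D and equal length")
        if run_symbols.size and run_symbols.max() >= ALPHABET_SIZE:
            raise ValueError("symbol code out of range (alphabet has 6 symbols)")
        if (run_lengths <= 0).any():
            raise ValueError("run lengths must be positive")
        if run_symbols.size > 1 and (run_symbols[1:] == run_symbols[:-1]).any():
            raise ValueError("adjacent runs must differ in symbol")
        self.run_symbols = run_symbols
        self.run_lengths = run_lengths
        counts = np.zeros(ALPHABET_SIZE, dtype=np.int64)
        np.add.at(counts, run_symbols, run_lengths)
        self.total_counts = counts

    @classmethod
    def from_symbols(cls, symbols: np.ndarray) -> "RleBwt":
        """Run-length encode a decoded symbol array."""
        symbols = np.asarray(symbols, dtype=np.uint8)
        if symbols.size == 0:
            return cls(np.empty(0, np.uint8), np.empty(0, np.int64))
        starts = np.flatnonzero(np.r_[True, symbols[1:] != symbols[:-1]])
        lengths = np.diff(np.r_[starts, symbols.size]).astype(np.int64)
        return cls(symbols[starts], lengths)

    def decode(self) -> np.ndarray:
        """Expand to the flat uint8 symbol array."""
        return np.repeat(self.run_symbols, self.run_lengths)

    @property
    def num_strings(self) -> int:
        return int(self.total_counts[0])

    def __len__(self) -> int:
        return int(self.total_counts.sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RleBwt):
            return NotImplemented
        return (
            np.array_equal(self.run_symbols, other.run_symbols)
            and np.array_equal(self.run_lengths, other.run_lengths)
        )

    def __repr__(self) -> str:
        return (
            f"RleBwt(length={len(self)}, strings={self.num_strings}, "
            f"runs={self.run_symbols.size})"
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _suffix_array(ranks: np.ndarray) -> np.ndarray:
    """Manber–Myers prefix doubling; ``ranks`` must make suffixes distinct
    eventually (guaranteed here by unique terminator ranks)."""
    n = ranks.size
    if n == 0:
        return np.empty(0, np.int64)
    rank = ranks.astype(np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, np.int64)
        key2[: n - step] = rank[step:]
        sa = np.lexsort((key2, rank))
        new = np.empty(n, np.int64)
        new[sa[0]] = 0
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new[sa[1:]] = np.cumsum(changed)
        rank = new
        if rank[sa[-1]] == n - 1:
            return sa
        step <<= 1


def build_msbwt(reads) -> RleBwt:
    """Build the multi-string BWT of a collection of A/C/G/N/T sequences.

    One ``$`` terminator per read; terminators sort before all bases with
    ties broken by read index, so the result is deterministic for a fixed
    input ordering.  An empty collection yields an empty BWT.
    """
    reads = list(reads)
    num = len(reads)
    if num == 0:
        return RleBwt(np.empty(0, np.uint8), np.empty(0, np.int64))

    encoded = []
    for i, read in enumerate(reads):
        if len(read) == 0:
            raise ValueError(f"read {i} is empty")
        try:
            encoded.append(encode(read))
        except ValueError as exc:
            raise ValueError(f"read {i}: {exc}") from None

    total = sum(e.size for e in encoded) + num
    codes = np.empty(total, np.uint8)      # true symbol codes ($ = 0)
    ranks = np.empty(total, np.int64)      # sort keys (distinct terminators)
    is_start = np.zeros(total, bool)
    pos = 0
    for i, e in enumerate(encoded):
        codes[pos : pos + e.size] = e
        ranks[pos : pos + e.size] = e.astype(np.int64) + num - 1
        is_start[pos] = True
        pos += e.size
        codes[pos] = 0
        ranks[pos] = i
        pos += 1

    sa = _suffix_array(ranks)
    # rotation preceding character: '$' of the same read at read starts,
    # otherwise the previous character of the concatenation
    bwt = np.where(is_start[sa], np.uint8(0), codes[sa - 1])
    return RleBwt.from_symbols(bwt)


# ---------------------------------------------------------------------------
# on-disk run-length dialect
# ---------------------------------------------------------------------------
#
# Flat byte array.  Each byte stores a symbol code in its low 3 bits and a
# base-32 run-length digit in its high 5 bits.  Consecutive bytes carrying
# the same symbol belong to one run; the j-th continuation digit contributes
# ``digit << (5*j)`` (little-endian base 32).  No header.

def save_rle(bwt: RleBwt, path) -> None:
    """Serialize to the flat byte dialect described in the module docs."""
    chunks = []
    for sym, length in zip(bwt.run_symbols.tolist(), bwt.run_lengths.tolist()):
        while True:
            chunks.append(sym | ((length & 31) << 3))
            length >>= 5
            if not length:
                break
    with open(path, "wb") as fh:
        fh.write(bytes(chunks))


def load_rle(path) -> RleBwt:
    """Parse the flat byte dialect; rejects undecodable symbol codes with
    the byte offset of the first offender."""
    with open(path, "rb") as fh:
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    if data.size == 0:
        return RleBwt(np.empty(0, np.uint8), np.empty(0, np.int64))
    syms = data & 7
    bad = syms >= ALPHABET_SIZE
    if bad.any():
        off = int(np.argmax(bad))
        raise ValueError(
            f"undecodable symbol code {int(syms[off])} at byte offset {off}"
        )
    digits = (data >> 3).astype(np.int64)
    starts = np.flatnonzero(np.r_[True, syms[1:] != syms[:-1]])
    place = np.arange(data.size, dtype=np.int64)
    place -= np.repeat(starts, np.diff(np.r_[starts, data.size]))
    if place.max() * 5 >= 63:
        raise ValueError("run length overflows 63 bits")
    lengths = np.add.reduceat(digits << (5 * place), starts)
    symbols = syms[starts]
    keep = lengths > 0
    # re-expand to guard against non-canonical inputs (zero-length runs)
    return RleBwt.from_symbols(np.repeat(symbols[keep], lengths[keep]))


# ---------------------------------------------------------------------------
# FM-index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerQuery:
    """A validated k-mer query over ``{A, C, G, N, T}``."""

    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("k-mer must have length >= 1")
        encode(self.sequence)  # raises on illegal symbols

    def __len__(self) -> int:
        return len(self.sequence)


class FmIndex:
    """Rank/occurrence structure over an :class:`RleBwt`.

    Subclasses provide ``rank`` and the batched kernels; everything built on
    top (k-mer counting, window counting, extension) lives here.
    """

    def __init__(self, bwt: RleBwt):
        self.total_counts = bwt.total_counts.copy()
        self.length = len(bwt)
        self.num_strings = bwt.num_strings
        # C array: offsets[c] = number of symbols strictly smaller than c
        self.alphabet_offsets = np.concatenate(
            ([0], np.cumsum(self.total_counts))
        ).astype(np.int64)

    # -- backend surface ----------------------------------------------------
    def rank(self, symbol: int, position: int) -> int:
        raise NotImplementedError

    def _count_patterns(self, pats: np.ndarray) -> np.ndarray:
        """Forward-strand backward-search count per row of ``pats``."""
        raise NotImplementedError

    def _window_counts_one_strand(self, codes: np.ndarray, k: int) -> np.ndarray:
        raise NotImplementedError

    # -- shared queries -----------------------------------------------------
    def count_codes(self, codes: np.ndarray) -> int:
        """Forward + reverse-complement count of an encoded k-mer."""
        pats = np.vstack([codes, revcomp_codes(codes)])
        counts = self._count_patterns(pats)
        return int(counts.sum())

    def count_kmer(self, kmer) -> int:
        """Total frequency of ``kmer`` (forward plus reverse complement).

        Accepts a string or a :class:`KmerQuery`; anything outside the
        ``{A,C,G,N,T}`` alphabet is rejected before searching.  A k-mer
        longer than every indexed read simply counts zero.
        """
        if isinstance(kmer, KmerQuery):
            kmer = kmer.sequence
        codes = encode(kmer)
        if codes.size == 0:
            raise ValueError("k-mer must have length >= 1")
        return self.count_codes(codes)

    def count_extensions(self, context: np.ndarray, k: int) -> np.ndarray:
        """Forward+RC counts of ``context + b`` for b in A,C,G,T.

        ``context`` holds the last ``k-1`` codes of the current k-mer; this
        is the implicit de Bruijn out-edge query used by traversal.
        """
        pats = np.empty((8, k), dtype=np.uint8)
        pats[:4, : k - 1] = context
        pats[:4, k - 1] = BASE_CODES
        for i in range(4):
            pats[4 + i] = revcomp_codes(pats[i])
        counts = self._count_patterns(pats)
        return counts[:4] + counts[4:]

    def window_counts(self, codes: np.ndarray, k: int) -> np.ndarray:
        """Forward+RC frequency of every length-``k`` window of ``codes``.

        Returns an empty array when the sequence is shorter than ``k``.
        """
        if codes.size < k:
            return np.empty(0, np.int64)
        fwd = self._window_counts_one_strand(codes, k)
        rc = self._window_counts_one_strand(revcomp_codes(codes), k)
        return fwd + rc[::-1]

    def extend_kmer(self, kmer, direction: str = "right"):
        """Frequencies of the four single-base de Bruijn extensions.

        ``right`` queries ``kmer[1:] + b``, ``left`` queries ``b + kmer[:-1]``
        for each base b in A<C<G<T order; zero-frequency entries are omitted.
        """
        if isinstance(kmer, KmerQuery):
            kmer = kmer.sequence
        if direction not in ("right", "left"):
            raise ValueError("direction must be 'right' or 'left'")
        codes = encode(kmer)
        k = codes.size
        out = []
        for b, ch in zip(BASE_CODES, "ACGT"):
            if direction == "right":
                cand = np.concatenate([codes[1:], [b]]).astype(np.uint8)
            else:
                cand = np.concatenate([[b], codes[:-1]]).astype(np.uint8)
            freq = self.count_codes(cand)
            if freq > 0:
                out.append((ch, freq))
        return out


class BitArrayFmIndex(FmIndex):
    """Default backend: per-symbol packed bit vectors with word-level
    prefix popcount checkpoints.  Fast ranks, ~6 bits + checkpoints per
    BWT symbol."""

    implementation = "bitarray"

    def __init__(self, bwt: RleBwt):
        super().__init__(bwt)
        symbols = bwt.decode()
        n_words = self.length // 64 + 1
        words = np.zeros((ALPHABET_SIZE, n_words), dtype=np.uint64)
        prefix = np.zeros((ALPHABET_SIZE, n_words), dtype=np.int64)
        for c in range(ALPHABET_SIZE):
            bits = np.packbits(symbols == c, bitorder="little")
            buf = np.zeros(n_words * 8, dtype=np.uint8)
            buf[: bits.size] = bits
            words[c] = buf.view(np.uint64)
            pc = np.bitwise_count(words[c]).astype(np.int64)
            prefix[c, 1:] = np.cumsum(pc)[:-1]
        self._words = words
        self._prefix = prefix

    def rank(self, symbol: int, position: int) -> int:
        if not (0 <= position <= self.length):
            raise IndexError("rank position out of range")
        return int(
            _kernels.rank_bits(self._words, self._prefix, symbol, position)
        )

    def _count_patterns(self, pats: np.ndarray) -> np.ndarray:
        out = np.empty(pats.shape[0], np.int64)
        _kernels.count_patterns_bits(
            self._words, self._prefix, self.alphabet_offsets,
            np.int64(self.length), pats, out,
        )
        return out

    def _window_counts_one_strand(self, codes: np.ndarray, k: int) -> np.ndarray:
        out = np.empty(codes.size - k + 1, np.int64)
        _kernels.window_counts_bits(
            self._words, self._prefix, self.alphabet_offsets,
            np.int64(self.length), codes, k, out,
        )
        return out


class SampledFmIndex(FmIndex):
    """Memory-light backend: occurrence checkpoints every ``sample_rate``
    symbols plus a scan of the decoded BWT inside the block."""

    implementation = "sampled"

    def __init__(self, bwt: RleBwt, sample_rate: int = 128):
        if sample_rate < 1:
            raise ValueError("sample_rate must be >= 1")
        super().__init__(bwt)
        self.sample_rate = int(sample_rate)
        symbols = bwt.decode()
        n_ck = self.length // self.sample_rate + 1
        checkpoints = np.zeros((ALPHABET_SIZE, n_ck), dtype=np.int64)
        for c in range(ALPHABET_SIZE):
            cs = np.cumsum(symbols == c)
            if n_ck > 1:
                checkpoints[c, 1:] = cs[self.sample_rate - 1 :: self.sample_rate][
                    : n_ck - 1
                ]
        self._bwt = symbols
        self._checkpoints = checkpoints

    def rank(self, symbol: int, position: int) -> int:
        if not (0 <= position <= self.length):
            raise IndexError("rank position out of range")
        return int(
            _kernels.rank_sampled(
                self._bwt, self._checkpoints, self.sample_rate, symbol, position
            )
        )

    def _count_patterns(self, pats: np.ndarray) -> np.ndarray:
        out = np.empty(pats.shape[0], np.int64)
        _kernels.count_patterns_sampled(
            self._bwt, self._checkpoints, self.sample_rate,
            self.alphabet_offsets, np.int64(self.length), pats, out,
        )
        return out

    def _window_counts_one_strand(self, codes: np.ndarray, k: int) -> np.ndarray:
        out = np.empty(codes.size - k + 1, np.int64)
        _kernels.window_counts_sampled(
            self._bwt, self._checkpoints, self.sample_rate,
            self.alphabet_offsets, np.int64(self.length), codes, k, out,
        )
        return out


def build_fm_index(
    bwt: RleBwt, implementation: str = "bitarray", sample_rate: int = 128
) -> FmIndex:
    """Construct an FM-index over ``bwt``.

    ``implementation`` selects the bit-array (default) or sampled backend;
    both answer every query identically.
    """
    if implementation == "bitarray":
        return BitArrayFmIndex(bwt)
    if implementation == "sampled":
        return SampledFmIndex(bwt, sample_rate=sample_rate)
    raise ValueError(f"unknown FM-index implementation {implementation!r}")
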