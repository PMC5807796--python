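"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the package:
rotation-sort BWT construction, substring-scan k-mer counting, explicit
de Bruijn graphs with exhaustive path enumeration, and a plain
quadratic-DP edit distance.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

_ORDER = {"$": 0, "A": 1, "C": 2, "G": 3, "N": 4, "T": 5}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_msbwt(reads: List[str]) -> str:
    """Sort all rotations of every read + '$'; terminators sort before
    bases, ties among terminators broken by read index."""
    rotations = []
    for idx, read in enumerate(reads):
        s = read.upper() + "$"
        for j in range(len(s)):
            rot = s[j:] + s[:j]
            key = tuple(
                (0, idx) if ch == "$" else (_ORDER[ch], -1) for ch in rot
            )
            rotations.append((key, rot[-1]))
    rotations.sort()
    return "".join(ch for _, ch in rotations)


def count_overlapping(hay: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def naive_count(reads: List[str], kmer: str) -> int:
    """Forward plus reverse-complement occurrences across all reads."""
    rc = revcomp(kmer)
    return sum(
        count_overlapping(r, kmer) + count_overlapping(r, rc) for r in reads
    )


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# explicit de Bruijn graph + exhaustive enumeration
# ---------------------------------------------------------------------------

class ExplicitDeBruijn:
    """Node set = every k-mer of the reads (and their reverse complements)
    whose forward+RC count reaches t; edges are (k-1)-overlaps between
    nodes."""

    def __init__(self, reads: List[str], k: int, t: int):
        self.k = k
        self.t = t
        counts: Dict[str, int] = {}
        for read in reads:
            for s in (read, revcomp(read)):
                for i in range(len(s) - k + 1):
                    km = s[i : i + k]
                    counts[km] = counts.get(km, 0)
        for km in counts:
            counts[km] = naive_count(reads, km)
        self.counts = {km: c for km, c in counts.items() if c >= t}

    def successors(self, kmer: str) -> List[Tuple[str, int]]:
        out = []
        for b in "ACGT":
            nxt = kmer[1:] + b
            if nxt in self.counts:
                out.append((b, self.counts[nxt]))
        return out

    def enumerate_bridge(
        self, seed: str, target: str, min_length: int, max_length: int
    ) -> List[str]:
        """All paths from seed that end with target within the length
        bounds; a branch stops the first time it hits the target.  No
        branch budget, no path cap — use fixtures where neither binds."""
        results: List[str] = []

        def walk(path: str):
            if len(path) >= min_length and path.endswith(target):
                results.append(path)
                return
            if len(path) >= max_length:
                return
            for b, _freq in self.successors(path[-self.k :]):
                walk(path + b)

        if seed in self.counts:
            walk(seed)
        return results

    def enumerate_extend(
        self, seed: str, min_length: int, max_length: int
    ) -> List[str]:
        """All maximal paths from seed (recorded on death or at
        max_length) of length at least min_length."""
        results: List[str] = []

        def walk(path: str):
            if len(path) >= max_length:
                if len(path) >= min_length:
                    results.append(path)
                return
            succ = self.successors(path[-self.k :])
            if not succ:
                if len(path) >= min_length:
                    results.append(path)
                return
            for b, _freq in succ:
                walk(path + b)

        if seed in self.counts:
            walk(seed)
        return results


def tile_reads(genome: str, length: int, step: int = 1) -> List[str]:
    """Error-free reads tiling a sequence (used to build dense fixtures)."""
    return [
        genome[i : i + length]
        for i in range(0, max(len(genome) - length + 1, 1), step)
    ]
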