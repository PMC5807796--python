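"""Truth-known synthetic data: genome, short reads, long reads.

The generator emulates the hybrid-correction setting at desk scale: a
random genome with a configurable planted repeat structure, low-error
substitution-only short reads (Illumina-like), and long reads with an
indel-dominated error profile (PacBio-CLR-like, default 15% total error at
sub:ins:del = 1:5:4).  Reads are drawn from both strands.  Every long read
carries a truth record — origin interval, strand and a CIGAR-like edit
trace relative to its oriented template — so corrections can be scored
without an external aligner.

Trace opcodes: ``=`` match, ``X`` substitution, ``I`` insertion (extra read
base), ``D`` deletion (template base missing from the read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

_BASES = "ACGT"


@dataclass(frozen=True)
class SimProfile:
    """Simulation parameters.

    Defaults are the package's reference scenario: a 50 kb genome carrying
    two copies of one 500 bp repeat, 100 bp short reads at 50x with 0.5%
    substitution error, and 4 kb long reads at 20x with 15% error split
    1:5:4 between substitutions, insertions and deletions.  Identical seeds
    give byte-identical datasets.
    """

    genome_length: int = 50_000
    repeat_count: int = 1
    repeat_length: int = 500
    repeat_copies: int = 2
    short_read_length: int = 100
    short_coverage: float = 50.0
    short_error_rate: float = 0.005
    long_read_length: int = 4_000
    long_coverage: float = 20.0
    long_error_rate: float = 0.15
    long_error_mix: Tuple[float, float, float] = (0.1, 0.5, 0.4)
    seed: int = 0

    def __post_init__(self):
        for rate in (self.short_error_rate, self.long_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        if abs(sum(self.long_error_mix) - 1.0) > 1e-9:
            raise ValueError("long_error_mix must sum to 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Origin of one long read: reference interval, strand, edit trace."""

    read_id: str
    start: int
    end: int
    strand: str  # '+' | '-'
    trace: str   # CIGAR-like over = X I D, relative to the oriented template


@dataclass
class SimResult:
    genome: str
    short_reads: List[Tuple[str, str]] = field(default_factory=list)
    long_reads: List[Tuple[str, str]] = field(default_factory=list)
    truth: List[TruthRecord] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]  # A<->T, C<->G under the 0123=ACGT mapping


def _plant_repeats(rng, genome: np.ndarray, profile: SimProfile) -> np.ndarray:
    g = genome.copy()
    length = profile.repeat_length
    if profile.repeat_count < 1 or profile.repeat_copies < 2 or length < 1:
        return g
    if length * profile.repeat_count * profile.repeat_copies > g.size // 2:
        raise ValueError("repeat specification exceeds half the genome")
    occupied: List[Tuple[int, int]] = []
    for _ in range(profile.repeat_count):
        unit = _random_seq(rng, length)
        for _ in range(profile.repeat_copies):
            for _attempt in range(1000):
                pos = int(rng.integers(0, g.size - length + 1))
                if all(pos + length <= s or pos >= e for s, e in occupied):
                    break
            else:  # pragma: no cover - pathological spec
                raise RuntimeError("could not place repeat copies")
            g[pos : pos + length] = unit
            occupied.append((pos, pos + length))
    return g


def _simulate_short(rng, genome: np.ndarray, profile: SimProfile):
    length = profile.short_read_length
    n = int(round(genome.size * profile.short_coverage / length))
    if n == 0 or genome.size < length:
        return []
    starts = rng.integers(0, genome.size - length + 1, size=n)
    minus = rng.random(n) < 0.5
    mat = genome[starts[:, None] + np.arange(length)]
    mat[minus] = 3 - mat[minus, ::-1]
    if profile.short_error_rate > 0:
        err = rng.random(mat.shape) < profile.short_error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.int8)
        mat[err] = (mat[err] + shift[err]) % 4
    return [(f"sr{i}", _to_str(row)) for i, row in enumerate(mat)]


def _mutate_long(rng, template: np.ndarray, ps: float, pi: float, pd: float):
    """Apply the long-read error process to one oriented template.

    Per template base: substitute with prob ``ps``, delete with prob ``pd``;
    independently, insert one random base after it with prob ``pi``.
    Returns (read codes, trace string)."""
    n = template.size
    u = rng.random(n)
    sub = u < ps
    dele = (u >= ps) & (u < ps + pd)
    ins = rng.random(n) < pi
    sub_shift = rng.integers(1, 4, size=n, dtype=np.int8)
    ins_base = rng.integers(0, 4, size=n, dtype=np.int8)
    out = []
    ops = []
    for i in range(n):
        if dele[i]:
            ops.append("D")
        elif sub[i]:
            out.append((template[i] + sub_shift[i]) % 4)
            ops.append("X")
        else:
            out.append(template[i])
            ops.append("=")
        if ins[i]:
            out.append(ins_base[i])
            ops.append("I")
    # run-length collapse the op string
    trace = []
    prev, run = None, 0
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                trace.append(f"{run}{prev}")
            prev, run = op, 1
    if prev is not None:
        trace.append(f"{run}{prev}")
    return np.array(out, dtype=np.int8), "".join(trace)


def simulate(profile: SimProfile) -> SimResult:
    """Generate a truth-known dataset from ``profile`` (deterministic per seed)."""
    rng = np.random.default_rng(profile.seed)
    genome = _plant_repeats(rng, _random_seq(rng, profile.genome_length), profile)
    result = SimResult(genome=_to_str(genome))
    result.short_reads = _simulate_short(rng, genome, profile)

    length = min(profile.long_read_length, genome.size)
    n = int(round(genome.size * profile.long_coverage / length)) if length else 0
    ps = profile.long_error_rate * profile.long_error_mix[0]
    pi = profile.long_error_rate * profile.long_error_mix[1]
    pd = profile.long_error_rate * profile.long_error_mix[2]
    for i in range(n):
        start = int(rng.integers(0, genome.size - length + 1))
        end = start + length
        strand = "-" if rng.random() < 0.5 else "+"
        template = genome[start:end]
        if strand == "-":
            template = _revcomp(template)
        read, trace = _mutate_long(rng, template, ps, pi, pd)
        rid = f"lr{i}"
        result.long_reads.append((rid, _to_str(read)))
        result.truth.append(TruthRecord(rid, start, end, strand, trace))
    return result


# -- truth sidecar (TSV) ------------------------------------------------------

def write_truth(path, records) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tstrand\ttrace\n")
        for rec in records:
            fh.write(f"{rec.read_id}\t{rec.start}\t{rec.end}\t{rec.strand}\t{rec.trace}\n")


def read_truth(path) -> List[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and not header.startswith("read_id\t"):
            raise ValueError(f"{path}: missing truth-map header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            rid, start, end, strand, trace = parts
            records.append(TruthRecord(rid, int(start), int(end), strand, trace))
    return records
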