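"""Per-locus correction statistics: sensitivity, specificity, gain.

Loci are positions of the reference template each long read was drawn from
(known exactly from the simulation truth map, so no external aligner is
involved).  Original and corrected reads are each globally aligned to the
oriented template; a template nucleotide is *correct* when it aligns to a
single identical read nucleotide, and *incorrect* when mismatched or
deleted in the read.  Comparing before/after status per locus gives the
2x2 table:

* TP — erroneous before, correct after (an error fixed)
* FP — correct before, erroneous after (an error introduced)
* FN — erroneous before and after (an error missed)
* TN — correct before and after

with sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and
gain = (TP-FP)/(TP+FN), the net fraction of input errors removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._align import locus_status
from ._codec import revcomp

__all__ = ["CorrectionStats", "score"]


@dataclass
class CorrectionStats:
    """Aggregate per-locus confusion counts and derived ratios."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    aligned_bases: int = 0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def gain(self) -> float:
        d = self.tp + self.fn
        return (self.tp - self.fp) / d if d else 0.0

    @property
    def errors_before(self) -> int:
        return self.tp + self.fn

    @property
    def errors_after(self) -> int:
        return self.fp + self.fn

    @property
    def identity_before(self) -> float:
        return (self.tn + self.fp) / self.aligned_bases if self.aligned_bases else 0.0

    @property
    def identity_after(self) -> float:
        return (self.tn + self.tp) / self.aligned_bases if self.aligned_bases else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "aligned_bases": self.aligned_bases,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "gain": self.gain,
            "errors_before": self.errors_before,
            "errors_after": self.errors_after,
            "identity_before": self.identity_before,
            "identity_after": self.identity_after,
        }


def score(
    original_reads: Sequence[str],
    corrected_reads: Sequence[str],
    truth,
    genome: str,
) -> CorrectionStats:
    """Score a correction run against the simulation truth.

    ``original_reads`` and ``corrected_reads`` must be in the same order as
    ``truth`` (one :class:`~lrcorrect.simulate.TruthRecord` per read).  A
    zero-length corrected read counts every locus of its origin interval as
    a missed error (FN).
    """
    if not (len(original_reads) == len(corrected_reads) == len(truth)):
        raise ValueError("original, corrected and truth must have equal length")
    stats = CorrectionStats()
    for orig, corr, rec in zip(original_reads, corrected_reads, truth):
        template = genome[rec.start : rec.end]
        if rec.strand == "-":
            template = revcomp(template)
        n = len(template)
        stats.aligned_bases += n
        if len(corr) == 0:
            stats.fn += n
            continue
        before = locus_status(template, orig)
        after = locus_status(template, corr)
        stats.tp += int(np.sum(~before & after))
        stats.fp += int(np.sum(before & ~after))
        stats.fn += int(np.sum(~before & ~after))
        stats.tn += int(np.sum(before & after))
    return stats
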