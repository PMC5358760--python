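"""Shared genomic primitives.

All coordinates are 0-based, half-open (BED convention). GFF3 output
converts to 1-based closed on write, nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A genomic interval, optionally stranded and named."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A Pol II transcription unit.

    ``start``/``end`` bound the full unit; the TSS sits at ``start`` on the
    plus strand and at ``end`` on the minus strand (boundary coordinates).
    ``tss_peak_fold`` models promoter-proximal pausing of Pol II relative to
    the gene-body level; ``body_level`` is the expected elongating-Pol II
    sampling weight per bp relative to intergenic background (1.0).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    tss_peak_fold: float = 1.0
    body_level: float = 1.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")
        if self.tss_peak_fold < 1:
            raise ValueError(f"gene {self.gene_id}: tss_peak_fold must be >= 1")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.contig, self.start, self.end, self.strand, self.gene_id)
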