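"""Shared genomic record types.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Peak:
    """An accessibility peak interval with optional test statistics."""

    chrom: str
    start: int
    end: int
    peak_id: str
    cell_type: str = ""
    condition: str = ""
    p_value: Optional[float] = None
    avg_log2fc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.peak_id}: start {self.start} >= end {self.end}"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; TSS is start for '+', end-1 for '-'."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Interval:
    """A bare interval (used for CNEs and gene windows)."""

    chrom: str
    start: int
    end: int
    name: str = ""


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>=1 bp overlap of two half-open intervals; bookended intervals do not overlap."""
    return a_start < b_end and b_start < a_end
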