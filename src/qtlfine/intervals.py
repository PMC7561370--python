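"""Genomic interval primitives and coordinate conventions.

All internal arithmetic uses 0-based half-open intervals; positions read
from VCF/GFF3 (1-based inclusive) are converted on input, and every report
column that exposes positions is rendered 1-based again.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} "
                "(start must be < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mbp(self) -> float:
        """Length in megabase pairs, rounded to one decimal as reported."""
        return round((self.end - self.start) / 1e6, 1)

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_1based(self) -> tuple[str, int, int]:
        """(chrom, start, end) in 1-based inclusive coordinates for reports."""
        return self.chrom, self.start + 1, self.end


def make_interval(chrom: str, start_mbp: float, end_mbp: float) -> GenomicInterval:
    """Build an interval from megabase coordinates as printed in the field.

    ``make_interval("chr4", 103.9, 117.5)`` gives the 13.6-Mbp congenic
    fragment; ``length_mbp`` reproduces the printed length.
    """
    if not start_mbp < end_mbp:
        raise ValueError(f"inverted or degenerate bounds: {start_mbp}–{end_mbp} Mbp")
    return GenomicInterval(chrom, int(round(start_mbp * 1e6)), int(round(end_mbp * 1e6)))


def hull(intervals: list[GenomicInterval]) -> GenomicInterval:
    """Smallest single interval covering all inputs (one chromosome only)."""
    if not intervals:
        raise ValueError("hull of empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"hull across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )
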