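"""Region-anchored genomic sequence with FASTA input/output.

Sequences for a chromosomal sub-region are carried together with the
0-based genomic offset of their first base, so gene models and variants
keep genomic coordinates while the on-disk FASTA stays small.  The region
is encoded in the FASTA header as ``chrom:start-end`` (1-based inclusive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass
class RegionSequence:
    """Sequence of ``[start0, start0+len)`` on one chromosome."""

    chrom: str
    start0: int
    seq: str

    @property
    def end0(self) -> int:
        return self.start0 + len(self.seq)

    def base_at(self, pos0: int) -> str:
        if not self.start0 <= pos0 < self.end0:
            raise IndexError(f"position {pos0} outside {self.chrom}:{self.start0}-{self.end0}")
        return self.seq[pos0 - self.start0]

    def slice(self, start0: int, end0: int) -> str:
        if start0 < self.start0 or end0 > self.end0:
            raise IndexError(
                f"slice {start0}-{end0} outside {self.chrom}:{self.start0}-{self.end0}"
            )
        return self.seq[start0 - self.start0 : end0 - self.start0]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds_seq: str) -> str:
    """Translate a coding sequence with the standard genetic code."""
    return str(Seq(cds_seq).translate())


def read_region_fasta(path: str | Path) -> RegionSequence:
    record = next(SeqIO.parse(str(path), "fasta"))
    m = _REGION_RE.match(record.id)
    if m:
        chrom, start1 = m.group("chrom"), int(m.group("start"))
        return RegionSequence(chrom, start1 - 1, str(record.seq).upper())
    return RegionSequence(record.id, 0, str(record.seq).upper())


def write_region_fasta(region: RegionSequence, path: str | Path) -> None:
    header = f"{region.chrom}:{region.start0 + 1}-{region.end0}"
    SeqIO.write([SeqRecord(Seq(region.seq), id=header, description="")], str(path), "fasta")
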