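"""Variant records, strain panels and VCF input/output.

A :class:`StrainPanel` names the assembly reference strain (implicit in the
VCF REF column), the background strains expected to share the reference
allele, and the carrier strain contributing the trait allele.  Multiallelic
VCF sites are decomposed into one record per alternate allele so the
strain-distribution-pattern test is well defined per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

MISSING = "."

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class from allele lengths: SNP iff both are single bases."""
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    if len(ref) < len(alt):
        return INSERTION
    if len(ref) > len(alt):
        return DELETION
    raise ValueError(f"unsupported multi-nucleotide substitution {ref}>{alt}")


@dataclass(frozen=True)
class StrainPanel:
    """The strains entering the distribution-pattern comparison."""

    reference_strain: str
    background_strains: tuple[str, ...]
    carrier_strain: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "background_strains", tuple(self.background_strains))
        names = [self.reference_strain, *self.background_strains, self.carrier_strain]
        if len(set(names)) != len(names):
            raise ValueError(f"panel strains not unique: {names}")

    @property
    def sample_strains(self) -> tuple[str, ...]:
        """Strains carried as VCF sample columns (reference is implicit)."""
        return (*self.background_strains, self.carrier_strain)


@dataclass(frozen=True)
class VariantRecord:
    """One site x alt-allele with per-strain calls.

    ``pos`` is 1-based as in the VCF; ``strain_calls`` maps strain name to
    the allele string it carries, or :data:`MISSING`.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    strain_calls: dict[str, str] = field(default_factory=dict)
    rsid: str | None = None

    @property
    def variant_class(self) -> str:
        return classify_alleles(self.ref_allele, self.alt_allele)

    @property
    def is_snp(self) -> bool:
        return self.variant_class == SNP

    @property
    def pos0(self) -> int:
        """0-based position of the first reference base."""
        return self.pos - 1


class VariantTable:
    """Position-sorted collection of :class:`VariantRecord`."""

    def __init__(self, records: Iterable[VariantRecord], panel: StrainPanel):
        self.records = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt_allele))
        self.panel = panel

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def in_region(self, chrom: str, start0: int, end0: int) -> list[VariantRecord]:
        """Records whose first base lies in the half-open region."""
        return [
            r for r in self.records if r.chrom == chrom and start0 <= r.pos0 < end0
        ]


def _decode_genotype(sample, alleles: tuple[str, ...]) -> str:
    """Homozygous genotype -> allele string; het or missing -> MISSING."""
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return MISSING
    if len(set(gt)) != 1:
        return MISSING
    return alleles[gt[0]]


def read_vcf(path: str | Path, panel: StrainPanel) -> VariantTable:
    """Read a VCF 4.x into a decomposed variant table.

    One sample column per panel strain is required (the reference strain is
    implicit as REF).  Multiallelic lines yield one record per ALT allele;
    a sample homozygous for a *different* alt than the record's own still
    reports that allele string, so discordance with REF stays visible.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for strain in panel.sample_strains:
            if strain not in samples:
                raise ValueError(f"panel strain {strain!r} absent from VCF header")
        for line_no, rec in enumerate(vcf, start=1):
            if rec.pos is None or rec.pos < 1:
                raise ValueError(f"malformed coordinate at data line {line_no}")
            alleles = tuple(rec.alleles)
            calls = {
                strain: _decode_genotype(rec.samples[strain], alleles)
                for strain in panel.sample_strains
            }
            for alt in rec.alts or ():
                classify_alleles(rec.ref, alt)  # reject MNPs early
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        strain_calls=dict(calls),
                        rsid=rec.id,
                    )
                )
    return VariantTable(records, panel)


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with one sample column per panel strain.

    Decomposed records are emitted as separate biallelic lines; reading the
    file back with :func:`read_vcf` reproduces positions, alleles and calls.
    """
    panel = table.panel
    strains = panel.sample_strains
    chroms = sorted({r.chrom for r in table.records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(strains)
            + "\n"
        )
        for rec in table.records:
            gts = []
            for strain in strains:
                call = rec.strain_calls.get(strain, MISSING)
                if call == MISSING:
                    gts.append("./.")
                elif call == rec.ref_allele:
                    gts.append("0/0")
                elif call == rec.alt_allele:
                    gts.append("1/1")
                else:  # allele from another decomposed alt at this site
                    gts.append("./.")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref_allele}\t"
                f"{rec.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
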