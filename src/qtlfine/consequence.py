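"""Variant-consequence classification against gene models.

Each variant receives, per overlapping gene, exactly one most-severe
category (severity: stop_gained > frameshift > missense > splice_region >
synonymous > other_exonic > intron > upstream); variants touching no gene
and no upstream window are intergenic.  Coding SNPs are translated with
the standard genetic code (strand-aware) and missense / stop calls carry a
protein change such as "P169L", numbered 1-based from the initiator
methionine.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .genes import GeneModel
from .sequences import RegionSequence, translate
from .variants import SNP, VariantRecord

STOP_GAINED = "stop_gained"
FRAMESHIFT = "frameshift"
MISSENSE = "missense"
SPLICE_REGION = "splice_region"
SYNONYMOUS = "synonymous"
OTHER_EXONIC = "other_exonic"
INTRON = "intron"
UPSTREAM = "upstream"
INTERGENIC = "intergenic"

#: most severe first
SEVERITY = (
    STOP_GAINED,
    FRAMESHIFT,
    MISSENSE,
    SPLICE_REGION,
    SYNONYMOUS,
    OTHER_EXONIC,
    INTRON,
    UPSTREAM,
)

_RANK = {c: i for i, c in enumerate(SEVERITY)}

#: Table-style summary row order
SUMMARY_ORDER = (
    INTRON,
    UPSTREAM,
    MISSENSE,
    SPLICE_REGION,
    FRAMESHIFT,
    STOP_GAINED,
    SYNONYMOUS,
    OTHER_EXONIC,
    INTERGENIC,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantRecord
    gene: str | None
    category: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if (self.category == INTERGENIC) != (self.gene is None):
            raise ValueError("intergenic iff gene is NONE")
        if self.protein_change is not None and self.category not in (MISSENSE, STOP_GAINED):
            raise ValueError("protein_change only for missense/stop_gained")


def _coding_positions(gene: GeneModel) -> list[int]:
    """Genomic 0-based positions of the CDS in coding (5'->3') order."""
    if not gene.cds:
        return []
    segs = sorted(gene.cds, key=lambda c: c[0].start)
    ordered = segs if gene.strand == "+" else list(reversed(segs))
    if ordered[0][1] != 0:
        raise ValueError(f"first CDS segment of {gene.gene_id} has phase {ordered[0][1]} != 0")
    positions: list[int] = []
    for iv, _phase in ordered:
        rng = range(iv.start, iv.end)
        positions.extend(rng if gene.strand == "+" else reversed(rng))
    return positions


def coding_sequence(gene: GeneModel, seq: RegionSequence) -> str:
    """The spliced, strand-corrected coding sequence of a gene."""
    bases = []
    for p in _coding_positions(gene):
        b = seq.base_at(p)
        bases.append(b if gene.strand == "+" else b.translate(_COMPLEMENT))
    return "".join(bases)


def _affected_span(variant: VariantRecord) -> tuple[int, int]:
    """Half-open genomic span of the bases the variant actually touches.

    SNPs touch their own base; deletions touch the deleted bases (the VCF
    anchor base is untouched); insertions are attributed to the anchor base.
    """
    if variant.variant_class == "deletion":
        return variant.pos0 + 1, variant.pos0 + len(variant.ref_allele)
    return variant.pos0, variant.pos0 + 1


def _splice_region_positions(gene: GeneModel) -> set[int]:
    """Positions in the splice-region bands of internal exon junctions.

    Exonic side: 1-3 bp from the junction; intronic side: 3-8 bp.
    """
    pos: set[int] = set()
    exons = gene.exons
    for i, e in enumerate(exons):
        if i < len(exons) - 1:  # junction at e.end (intron to the right)
            pos.update(range(e.end - 3, e.end))          # exonic, dist 1-3
            pos.update(range(e.end + 2, e.end + 8))      # intronic, dist 3-8
        if i > 0:  # junction at e.start (intron to the left)
            pos.update(range(e.start, e.start + 3))      # exonic, dist 1-3
            pos.update(range(e.start - 8, e.start - 2))  # intronic, dist 3-8
    return pos


def _snp_coding_category(
    gene: GeneModel, variant: VariantRecord, seq: RegionSequence
) -> tuple[str, str | None]:
    cpos_list = _coding_positions(gene)
    index = {p: i for i, p in enumerate(cpos_list)}
    cpos = index[variant.pos0]
    ref_base = seq.base_at(variant.pos0)
    if ref_base != variant.ref_allele:
        raise ValueError(
            f"reference allele mismatch at {variant.chrom}:{variant.pos} "
            f"(sequence {ref_base}, variant {variant.ref_allele})"
        )
    codon_i = cpos // 3
    offset = cpos % 3
    codon_pos = cpos_list[3 * codon_i : 3 * codon_i + 3]
    if len(codon_pos) < 3:  # trailing partial codon (incomplete ORF)
        return OTHER_EXONIC, None
    ref_codon = [seq.base_at(p) for p in codon_pos]
    alt_codon = list(ref_codon)
    alt_codon[offset] = variant.alt_allele
    if gene.strand == "-":
        ref_codon = [b.translate(_COMPLEMENT) for b in ref_codon]
        alt_codon = [b.translate(_COMPLEMENT) for b in alt_codon]
    ref_aa = translate("".join(ref_codon))
    alt_aa = translate("".join(alt_codon))
    if alt_aa == ref_aa:
        return SYNONYMOUS, None
    change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    return (STOP_GAINED, change) if alt_aa == "*" else (MISSENSE, change)


def _gene_category(
    gene: GeneModel, variant: VariantRecord, seq: RegionSequence | None
) -> tuple[str, str | None]:
    """Most-severe category of a variant overlapping this gene's span."""
    span = _affected_span(variant)
    candidates: list[tuple[str, str | None]] = []

    cds_hit = any(c.start < span[1] and span[0] < c.end for c, _ in gene.cds)
    exon_hit = any(e.start < span[1] and span[0] < e.end for e in gene.exons)

    if variant.variant_class == SNP:
        if cds_hit:
            if seq is None:
                raise ValueError("sequence context required for coding SNP classification")
            candidates.append(_snp_coding_category(gene, variant, seq))
        elif exon_hit:
            candidates.append((OTHER_EXONIC, None))
    else:  # indel
        if cds_hit:
            shift = abs(len(variant.alt_allele) - len(variant.ref_allele))
            candidates.append((FRAMESHIFT, None) if shift % 3 else (OTHER_EXONIC, None))
        elif exon_hit:
            candidates.append((OTHER_EXONIC, None))

    splice = _splice_region_positions(gene)
    if any(p in splice for p in range(*span)):
        candidates.append((SPLICE_REGION, None))

    if not candidates:
        candidates.append((INTRON, None))
    return min(candidates, key=lambda c: _RANK[c[0]])


def _upstream_of(gene: GeneModel, variant: VariantRecord, upstream_window: int) -> bool:
    span = _affected_span(variant)
    if gene.strand == "+":
        lo, hi = gene.interval.start - upstream_window, gene.interval.start
    else:
        lo, hi = gene.interval.end, gene.interval.end + upstream_window
    return variant.chrom == gene.interval.chrom and span[0] < hi and lo < span[1]


def classify_variant(
    variant: VariantRecord,
    gene_models: list[GeneModel],
    seq: RegionSequence | None = None,
    upstream_window: int = 5000,
) -> list[ConsequenceCall]:
    """Classify one variant against all gene models.

    One call per overlapping gene (most-severe category), one upstream call
    per gene whose strand-aware upstream window covers the variant, and a
    single intergenic call when nothing applies.
    """
    span = _affected_span(variant)
    calls: list[ConsequenceCall] = []
    for gene in gene_models:
        iv = gene.interval
        if variant.chrom == iv.chrom and span[0] < iv.end and iv.start < span[1]:
            category, change = _gene_category(gene, variant, seq)
            calls.append(ConsequenceCall(variant, gene.gene_id, category, change))
        elif _upstream_of(gene, variant, upstream_window):
            calls.append(ConsequenceCall(variant, gene.gene_id, UPSTREAM))
    if not calls:
        calls.append(ConsequenceCall(variant, None, INTERGENIC))
    return calls


def classify_table(
    variants,
    gene_models: list[GeneModel],
    seq: RegionSequence | None = None,
    upstream_window: int = 5000,
) -> list[ConsequenceCall]:
    calls: list[ConsequenceCall] = []
    for v in variants:
        calls.extend(classify_variant(v, gene_models, seq, upstream_window))
    return calls


def consequence_summary(calls: list[ConsequenceCall]) -> pd.DataFrame:
    """Per-category counts of SNPs, indels and distinct genes."""
    snps = defaultdict(int)
    indels = defaultdict(int)
    genes = defaultdict(set)
    for c in calls:
        if c.variant.variant_class == SNP:
            snps[c.category] += 1
        else:
            indels[c.category] += 1
        if c.gene is not None:
            genes[c.category].add(c.gene)
    rows = [
        {
            "category": cat,
            "n_snps": snps.get(cat, 0),
            "n_indels": indels.get(cat, 0),
            "n_genes": len(genes.get(cat, ())),
        }
        for cat in SUMMARY_ORDER
    ]
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[ConsequenceCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "rsid": v.rsid or ".",
                "variant_class": v.variant_class,
                "gene": c.gene or ".",
                "category": c.category,
                "protein_change": c.protein_change or ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "rsid",
            "variant_class", "gene", "category", "protein_change",
        ],
    )
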