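"""Windowed strain-distribution-pattern scan and polymorphic-block merging.

The chromosomal region is dissected into non-overlapping 250-kb windows
anchored at the region start.  Per window, SNPs matching the pattern
"background strains = reference != carrier" (the B6 = NZO != DBA rule) are
counted; a window whose pattern count exceeds the threshold (strictly, by
default 100) is polymorphic, and maximal runs of polymorphic windows merge
into haplotype blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval
from .variants import MISSING, StrainPanel, VariantRecord


@dataclass(frozen=True)
class WindowResult:
    interval: GenomicInterval
    total_snps: int
    pattern_snps: int
    polymorphic: bool


@dataclass(frozen=True)
class HaplotypeBlock:
    interval: GenomicInterval
    n_windows: int
    total_pattern_snps: int


def pattern_match(
    record: VariantRecord,
    panel: StrainPanel,
    require_background_equals_reference: bool = True,
) -> bool:
    """True iff the SNP follows the carrier-specific distribution pattern.

    Every background strain must carry the reference allele (or, with
    ``require_background_equals_reference=False``, merely agree with each
    other) while the carrier strain differs from the reference.  Any
    MISSING call among the involved strains fails the pattern.
    """
    if not record.is_snp:
        raise ValueError("pattern_match is defined for SNPs only")
    calls = record.strain_calls
    for strain in panel.sample_strains:
        if strain not in calls:
            raise ValueError(f"panel strain {strain!r} absent from strain_calls")
    bg = [calls[s] for s in panel.background_strains]
    carrier = calls[panel.carrier_strain]
    if carrier == MISSING or MISSING in bg:
        return False
    if require_background_equals_reference:
        if any(b != record.ref_allele for b in bg):
            return False
    else:
        if len(set(bg)) > 1:
            return False
    return carrier != record.ref_allele


def window_scan(
    variants,
    region: GenomicInterval,
    panel: StrainPanel,
    window_size: int = 250_000,
    min_count: int = 100,
    strict: bool = True,
    require_background_equals_reference: bool = True,
) -> list[WindowResult]:
    """Count total and pattern-matching SNPs in tiling windows.

    Windows are half-open and anchored at the region start; the final
    partial window is scored against the same absolute threshold.  A SNP
    sitting exactly on a window boundary belongs to the right-hand window.
    Indels are excluded from all counts.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    n_windows = (len(region) + window_size - 1) // window_size
    total = [0] * n_windows
    pattern = [0] * n_windows
    for rec in variants:
        if not rec.is_snp:
            continue
        if rec.chrom != region.chrom or not (region.start <= rec.pos0 < region.end):
            continue
        w = (rec.pos0 - region.start) // window_size
        total[w] += 1
        if pattern_match(rec, panel, require_background_equals_reference):
            pattern[w] += 1
    results = []
    for w in range(n_windows):
        start = region.start + w * window_size
        end = min(start + window_size, region.end)
        poly = pattern[w] > min_count if strict else pattern[w] >= min_count
        results.append(
            WindowResult(GenomicInterval(region.chrom, start, end), total[w], pattern[w], poly)
        )
    return results


def merge_blocks(windows: list[WindowResult]) -> list[HaplotypeBlock]:
    """Merge maximal runs of consecutive polymorphic windows into blocks."""
    blocks: list[HaplotypeBlock] = []
    run: list[WindowResult] = []

    def flush() -> None:
        if run:
            blocks.append(
                HaplotypeBlock(
                    GenomicInterval(run[0].interval.chrom, run[0].interval.start, run[-1].interval.end),
                    n_windows=len(run),
                    total_pattern_snps=sum(w.pattern_snps for w in run),
                )
            )
            run.clear()

    for w in windows:
        if w.polymorphic:
            run.append(w)
        else:
            flush()
    flush()
    return blocks


def write_windows_tsv(windows: list[WindowResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttotal_snps\tpattern_snps\tpolymorphic\n")
        for w in windows:
            chrom, s1, e1 = w.interval.to_1based()
            fh.write(f"{chrom}\t{s1}\t{e1}\t{w.total_snps}\t{w.pattern_snps}\t{w.polymorphic}\n")


def write_blocks_bed(blocks: list[HaplotypeBlock], path) -> None:
    """BED (0-based half-open) of merged polymorphic blocks."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks, 1):
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}\t"
                f"block{i}\t{b.total_pattern_snps}\t.\n"
            )
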