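"""Interval <-> gene-model intersection and biotype accounting."""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .intervals import GenomicInterval
from .genes import BIOTYPES, GeneModel


def genes_in_interval(
    genes: list[GeneModel],
    interval: GenomicInterval,
    containment: bool = False,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Genes overlapping (default) or fully contained in the interval.

    Returns the subset sorted by start together with per-biotype counts
    (all four categories present, zero-filled), which sum to the subset
    size by construction.
    """
    if containment:
        subset = [g for g in genes if interval.contains_interval(g.interval)]
    else:
        subset = [g for g in genes if g.interval.overlaps(interval)]
    subset.sort(key=lambda g: g.interval.start)
    counts = Counter(g.biotype for g in subset)
    return subset, {b: counts.get(b, 0) for b in BIOTYPES}


def genes_in_blocks(genes: list[GeneModel], blocks, containment: bool = False) -> list[GeneModel]:
    """Union of genes_in_interval over all block intervals, de-duplicated."""
    seen: dict[str, GeneModel] = {}
    for block in blocks:
        iv = block.interval if hasattr(block, "interval") else block
        subset, _ = genes_in_interval(genes, iv, containment=containment)
        for g in subset:
            seen[g.gene_id] = g
    return sorted(seen.values(), key=lambda g: (g.interval.chrom, g.interval.start))


def gene_report(genes: list[GeneModel], blocks) -> pd.DataFrame:
    """Per-gene table with 1-based coordinates and block membership."""
    in_block = {g.gene_id for g in genes_in_blocks(genes, blocks)}
    rows = []
    for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        chrom, start1, end1 = g.interval.to_1based()
        rows.append(
            {
                "gene_id": g.gene_id,
                "name": g.gene_name,
                "biotype": g.biotype,
                "chrom": chrom,
                "start": start1,
                "end": end1,
                "in_block": g.gene_id in in_block,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "name", "biotype", "chrom", "start", "end", "in_block"])
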