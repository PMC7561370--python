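"""Gene models, biotype mapping and GFF3 input/output.

Gene annotation biotypes are collapsed into the four categories used for
interval accounting — annotated genes, predicted gene models, pseudogenes
and non-coding RNAs — through a shipped, user-overridable mapping table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .intervals import GenomicInterval

ANNOTATED = "annotated_gene"
GENE_MODEL = "gene_model"
PSEUDOGENE = "pseudogene"
NONCODING = "noncoding_RNA"

BIOTYPES = (ANNOTATED, GENE_MODEL, PSEUDOGENE, NONCODING)

#: Default raw-biotype -> category map; substring fallbacks below cover the rest.
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": ANNOTATED,
    "predicted_gene": GENE_MODEL,
    "TEC": GENE_MODEL,
    "pseudogene": PSEUDOGENE,
    "processed_pseudogene": PSEUDOGENE,
    "unprocessed_pseudogene": PSEUDOGENE,
    "lincRNA": NONCODING,
    "lncRNA": NONCODING,
    "miRNA": NONCODING,
    "snoRNA": NONCODING,
    "snRNA": NONCODING,
    "rRNA": NONCODING,
    "misc_RNA": NONCODING,
    "antisense": NONCODING,
}


def map_biotype(raw: str, table: dict[str, str] | None = None) -> str:
    """Collapse a raw annotation biotype into one of the four categories."""
    table = DEFAULT_BIOTYPE_MAP if table is None else table
    if raw in BIOTYPES:
        return raw
    if raw in table:
        return table[raw]
    if "pseudogene" in raw:
        return PSEUDOGENE
    if "RNA" in raw:
        return NONCODING
    return GENE_MODEL


@dataclass
class GeneModel:
    """A gene with its exon/CDS structure on one strand.

    ``cds`` is ordered by genomic start and carries per-segment frame phase
    (bases to skip before the first complete codon of that segment).
    """

    gene_id: str
    gene_name: str
    biotype: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unmapped biotype {self.biotype!r} for {self.gene_id}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds = sorted(self.cds, key=lambda c: c[0].start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        for e in self.exons:
            if not self.interval.contains_interval(e):
                raise ValueError(f"exon outside gene interval in {self.gene_id}")
        for c, _phase in self.cds:
            if not any(e.contains_interval(c) for e in self.exons):
                raise ValueError(f"CDS segment outside exons in {self.gene_id}")

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def tss(self) -> int:
        """0-based transcription start position (strand-aware)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def cds_length(self) -> int:
        return sum(len(c) for c, _ in self.cds)


def read_gff3(path: str | Path, biotype_map: dict[str, str] | None = None) -> list[GeneModel]:
    """Assemble gene models from a GFF3 file by Parent attributes.

    Exons/CDS may hang off the gene directly or via one transcript level.
    A CDS without a resolvable parent gene, or mixed strands within one
    gene's features, is a fatal error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    feature_to_gene: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        feature_to_gene[g.id] = g.id
        for t in db.children(g, level=1):
            feature_to_gene[t.id] = g.id

    parts: dict[str, dict[str, list]] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            gene_ids = {feature_to_gene.get(p) for p in parents}
            gene_ids.discard(None)
            if not gene_ids:
                raise ValueError(f"{ftype} at {feat.seqid}:{feat.start} has no parent gene")
            for gid in gene_ids:
                bucket = parts.setdefault(gid, {"exon": [], "CDS": []})
                bucket[ftype].append(feat)

    for g in db.features_of_type("gene"):
        bucket = parts.get(g.id, {"exon": [], "CDS": []})
        strands = {g.strand} | {f.strand for fs in bucket.values() for f in fs}
        if len(strands) != 1:
            raise ValueError(f"mixed strands within gene {g.id}")
        raw_biotype = (
            g.attributes.get("biotype", g.attributes.get("gene_biotype", ["protein_coding"]))
        )[0]
        exons = [
            GenomicInterval(f.seqid, f.start - 1, f.end) for f in bucket["exon"]
        ]
        cds = [
            (GenomicInterval(f.seqid, f.start - 1, f.end),
             int(f.frame) if f.frame not in (None, ".") else 0)
            for f in bucket["CDS"]
        ]
        if bucket["CDS"] and any(f.frame in (None, ".") for f in bucket["CDS"]):
            raise ValueError(f"CDS without phase in gene {g.id}")
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                gene_name=name,
                biotype=map_biotype(raw_biotype, biotype_map),
                interval=GenomicInterval(g.seqid, g.start - 1, g.end),
                strand=g.strand,
                exons=exons,
                cds=cds,
            )
        )
    genes.sort(key=lambda gm: (gm.interval.chrom, gm.interval.start))
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (gene -> mRNA -> exon/CDS hierarchy)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda gm: (gm.interval.chrom, gm.interval.start)):
            chrom, start1, end1 = g.interval.to_1based()
            attrs = f"ID={g.gene_id};Name={g.gene_name};biotype={g.biotype}"
            fh.write(
                f"{chrom}\tqtlfine\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{chrom}\tqtlfine\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                _, es, ee = e.to_1based()
                fh.write(
                    f"{chrom}\tqtlfine\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (c, phase) in enumerate(g.cds, 1):
                _, cs, ce = c.to_1based()
                fh.write(
                    f"{chrom}\tqtlfine\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t{phase}\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )
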