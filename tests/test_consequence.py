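"""Consequence-classifier checks, including an exhaustive per-base oracle.

The oracle classifies by brute force: it rebuilds the entire coding
sequence of the mutated gene, translates the whole protein and compares it
with the reference protein, and derives interval memberships by scanning
base-by-base — an independent route from the classifier's codon-local
arithmetic.
"""

import numpy as np
import pytest

from qtlfine.consequence import (
    FRAMESHIFT,
    INTERGENIC,
    INTRON,
    MISSENSE,
    OTHER_EXONIC,
    SPLICE_REGION,
    STOP_GAINED,
    SYNONYMOUS,
    UPSTREAM,
    _RANK,
    classify_variant,
    coding_sequence,
    consequence_summary,
)
from qtlfine.genes import ANNOTATED, NONCODING, GeneModel
from qtlfine.intervals import GenomicInterval
from qtlfine.sequences import RegionSequence, revcomp, translate
from qtlfine.variants import VariantRecord


def make_gene(chrom="chr4", strand="+"):
    """A 5-exon coding gene on [1000, 2000) with UTR flanks."""
    exons = [
        GenomicInterval(chrom, 1000, 1100),
        GenomicInterval(chrom, 1200, 1310),
        GenomicInterval(chrom, 1400, 1520),
        GenomicInterval(chrom, 1600, 1720),
        GenomicInterval(chrom, 1800, 2000),
    ]
    cds_iv = [
        GenomicInterval(chrom, 1040, 1100),   # 60
        GenomicInterval(chrom, 1200, 1310),   # 110
        GenomicInterval(chrom, 1400, 1520),   # 120
        GenomicInterval(chrom, 1600, 1720),   # 120
        GenomicInterval(chrom, 1800, 1891),   # 91 -> total 501, %3 == 0
    ]
    ordered = cds_iv if strand == "+" else list(reversed(cds_iv))
    cds, consumed = [], 0
    for c in ordered:
        cds.append((c, (3 - consumed % 3) % 3))
        consumed += len(c)
    cds.sort(key=lambda t: t[0].start)
    return GeneModel(
        "g1", "g1", ANNOTATED, GenomicInterval(chrom, 1000, 2000), strand, exons, cds
    )


def make_seq(seed=0, start0=0, length=3000, chrom="chr4"):
    rng = np.random.default_rng(seed)
    return RegionSequence(
        chrom, start0, "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    )


def snv(pos1, ref, alt, chrom="chr4"):
    return VariantRecord(chrom, pos1, ref, alt, {"NZO": ref, "DBA": alt})


class TestCodingSnp:
    def test_p169l_rendering(self):
        """A C->T at the middle base of the CCA codon 169 renders P169L."""
        chrom = "chr4"
        exon = GenomicInterval(chrom, 0, 600)
        gene = GeneModel(
            "t", "t", ANNOTATED, GenomicInterval(chrom, 0, 600), "+",
            [exon], [(GenomicInterval(chrom, 0, 600), 0)],
        )
        seq = make_seq(seed=1, length=600)
        s = list(seq.seq)
        s[504:507] = list("CCA")  # codon 169 (0-based coding pos 504-506)
        seq = RegionSequence(chrom, 0, "".join(s))
        (call,) = classify_variant(snv(506, "C", "T"), [gene], seq)
        assert call.category == MISSENSE and call.protein_change == "P169L"

    def test_synonymous_third_position(self):
        gene = make_gene()
        seq = make_seq()
        s = list(seq.seq)
        s[1040:1043] = list("CTT")  # Leu; CTT->CTC stays Leu
        seq = RegionSequence("chr4", 0, "".join(s))
        (call,) = classify_variant(snv(1043, "T", "C"), [gene], seq)
        assert call.category == SYNONYMOUS

    def test_stop_gained_carries_protein_change(self):
        gene = make_gene()
        seq = make_seq()
        s = list(seq.seq)
        s[1043:1046] = list("TGG")  # Trp codon 2; TGG->TGA is a stop
        seq = RegionSequence("chr4", 0, "".join(s))
        (call,) = classify_variant(snv(1046, "G", "A"), [gene], seq)
        assert call.category == STOP_GAINED and call.protein_change == "W2*"

    def test_reference_mismatch_fatal(self):
        gene = make_gene()
        seq = make_seq()
        ref = seq.base_at(1050)
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        with pytest.raises(ValueError, match="mismatch"):
            classify_variant(snv(1051, wrong, ref), [gene], seq)


class TestIndels:
    def test_one_bp_deletion_in_cds_is_frameshift(self):
        gene, seq = make_gene(), make_seq()
        anchor0 = 1050
        ref = seq.slice(anchor0, anchor0 + 2)
        (call,) = classify_variant(snv(anchor0 + 1, ref, ref[0]), [gene], seq)
        assert call.category == FRAMESHIFT

    def test_three_bp_deletion_in_frame(self):
        gene, seq = make_gene(), make_seq()
        anchor0 = 1050
        ref = seq.slice(anchor0, anchor0 + 4)
        (call,) = classify_variant(snv(anchor0 + 1, ref, ref[0]), [gene], seq)
        assert call.category == OTHER_EXONIC

    def test_insertion_in_cds_is_frameshift(self):
        gene, seq = make_gene(), make_seq()
        ref = seq.base_at(1050)
        (call,) = classify_variant(snv(1051, ref, ref + "TT"), [gene], seq)
        assert call.category == FRAMESHIFT


class TestNoncodingCategories:
    def test_upstream_within_window(self):
        gene, seq = make_gene(), make_seq()
        pos0 = 1000 - 900  # 900 bp 5' of the TSS
        ref = seq.base_at(pos0)
        alt = "A" if ref != "A" else "G"
        (call,) = classify_variant(snv(pos0 + 1, ref, alt), [gene], seq, upstream_window=5000)
        assert call.category == UPSTREAM
        calls = classify_variant(snv(pos0 + 1, ref, alt), [gene], seq, upstream_window=100)
        assert calls[0].category == INTERGENIC and calls[0].gene is None

    def test_deep_intron(self):
        gene, seq = make_gene(), make_seq()
        (call,) = classify_variant(snv(1151, seq.base_at(1150), "A" if seq.base_at(1150) != "A" else "C"), [gene], seq)
        assert call.category == INTRON

    def test_splice_region_bands(self):
        gene, seq = make_gene(), make_seq()
        # 4th intronic base after the exon ending at 1100 (0-based 1102)
        pos0 = 1103
        ref = seq.base_at(pos0)
        (call,) = classify_variant(snv(pos0 + 1, ref, "A" if ref != "A" else "C"), [gene], seq)
        assert call.category == SPLICE_REGION

    def test_noncoding_gene_exonic_snp(self):
        chrom = "chr4"
        gene = GeneModel(
            "nc", "nc", NONCODING, GenomicInterval(chrom, 1000, 1500), "+",
            [GenomicInterval(chrom, 1000, 1500)], [],
        )
        seq = make_seq()
        ref = seq.base_at(1100)
        (call,) = classify_variant(snv(1101, ref, "A" if ref != "A" else "C"), [gene], seq)
        assert call.category == OTHER_EXONIC


class TestTranslationIdentity:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_planted_cds_translates_to_planted_protein(self, strand):
        """Writing a known ORF into the genome and reading it back through
        the gene model reproduces the planted protein."""
        gene = make_gene(strand=strand)
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
        protein = (protein * 2)[:166]  # 501 coding bases = 167 codons incl. stop
        codon = {
            "M": "ATG", "K": "AAA", "T": "ACT", "A": "GCT", "Y": "TAT", "I": "ATT",
            "Q": "CAA", "R": "CGT", "S": "TCT", "F": "TTT", "V": "GTT", "H": "CAT",
            "L": "CTT", "E": "GAA", "G": "GGT", "P": "CCT", "D": "GAT", "N": "AAT",
            "W": "TGG", "C": "TGT",
        }
        cds_nt = "".join(codon[a] for a in protein) + "TAA"
        if strand == "-":
            cds_nt_genomic = revcomp(cds_nt)
        else:
            cds_nt_genomic = cds_nt
        seq = make_seq(seed=3)
        s = list(seq.seq)
        cds_positions = sorted(
            p for c, _ in gene.cds for p in range(c.start, c.end)
        )
        for p, b in zip(cds_positions, cds_nt_genomic):
            s[p] = b
        seq = RegionSequence("chr4", 0, "".join(s))
        assert translate(coding_sequence(gene, seq)) == protein + "*"


class TestSummary:
    def test_empty_calls_all_zero(self):
        table = consequence_summary([])
        assert (table[["n_snps", "n_indels", "n_genes"]].to_numpy() == 0).all()

    def test_manual_tallies(self):
        gene, seq = make_gene(), make_seq()
        calls = []
        for pos0 in (1130, 1160):  # two intronic SNPs, one gene
            ref = seq.base_at(pos0)
            calls += classify_variant(snv(pos0 + 1, ref, "A" if ref != "A" else "C"), [gene], seq)
        anchor0 = 1050
        ref2 = seq.slice(anchor0, anchor0 + 2)
        calls += classify_variant(snv(anchor0 + 1, ref2, ref2[0]), [gene], seq)
        table = consequence_summary(calls).set_index("category")
        assert tuple(table.loc[INTRON]) == (2, 0, 1)
        assert tuple(table.loc[FRAMESHIFT]) == (0, 1, 1)


# ---------------------------------------------------------------------------
# exhaustive oracle


def oracle_category(gene: GeneModel, variant: VariantRecord, seq: RegionSequence) -> str:
    """Brute-force classification via whole-protein comparison and
    base-by-base interval membership."""
    if variant.variant_class == "deletion":
        touched = set(range(variant.pos0 + 1, variant.pos0 + len(variant.ref_allele)))
    else:
        touched = {variant.pos0}
    gene_span = set(range(gene.interval.start, gene.interval.end))
    if not touched & gene_span:
        if gene.strand == "+":
            window = set(range(gene.interval.start - 5000, gene.interval.start))
        else:
            window = set(range(gene.interval.end, gene.interval.end + 5000))
        return UPSTREAM if touched & window else INTERGENIC
    exonic = {p for e in gene.exons for p in range(e.start, e.end)}
    cds_pos = {p for c, _ in gene.cds for p in range(c.start, c.end)}
    splice = set()
    exons = gene.exons
    for i, e in enumerate(exons):
        for d in (1, 2, 3):
            if i < len(exons) - 1:
                splice.add(e.end - d)
            if i > 0:
                splice.add(e.start + d - 1)
        for d in (3, 4, 5, 6, 7, 8):
            if i < len(exons) - 1:
                splice.add(e.end + d - 1)
            if i > 0:
                splice.add(e.start - d)

    candidates = []
    if touched & cds_pos:
        if variant.variant_class == "SNP":
            ref_prot = translate(coding_sequence(gene, seq))
            mutated = list(seq.seq)
            mutated[variant.pos0 - seq.start0] = variant.alt_allele
            alt_prot = translate(
                coding_sequence(gene, RegionSequence(seq.chrom, seq.start0, "".join(mutated)))
            )
            diff = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
            if not diff:
                candidates.append(SYNONYMOUS)
            else:
                (i,) = diff  # a SNP changes at most one codon
                candidates.append(STOP_GAINED if alt_prot[i] == "*" else MISSENSE)
        else:
            shift = abs(len(variant.alt_allele) - len(variant.ref_allele))
            candidates.append(FRAMESHIFT if shift % 3 else OTHER_EXONIC)
    elif touched & exonic:
        candidates.append(OTHER_EXONIC)
    if touched & splice:
        candidates.append(SPLICE_REGION)
    if not candidates:
        candidates.append(INTRON)
    return min(candidates, key=lambda c: _RANK[c])


class TestExhaustiveOracle:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_snvs_and_indels_agree_with_oracle(self, strand):
        gene = make_gene(strand=strand)
        seq = make_seq(seed=9)
        mism = []
        for pos0 in range(1000, 2000):
            ref = seq.base_at(pos0)
            # every alternate base
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = snv(pos0 + 1, ref, alt)
                (call,) = classify_variant(v, [gene], seq)
                exp = oracle_category(gene, v, seq)
                if call.category != exp:
                    mism.append((pos0, ref, alt, call.category, exp))
            # deletions of 1-3 bp (anchor + deleted bases)
            for dlen in (1, 2, 3):
                if pos0 + 1 + dlen > seq.end0:
                    continue
                refdel = seq.slice(pos0, pos0 + 1 + dlen)
                v = snv(pos0 + 1, refdel, refdel[0])
                (call,) = classify_variant(v, [gene], seq)
                exp = oracle_category(gene, v, seq)
                if call.category != exp:
                    mism.append((pos0, "del", dlen, call.category, exp))
            # insertions of 1-3 bp at the anchor
            for ins in ("T", "TG", "TGC"):
                v = snv(pos0 + 1, ref, ref + ins)
                (call,) = classify_variant(v, [gene], seq)
                exp = oracle_category(gene, v, seq)
                if call.category != exp:
                    mism.append((pos0, "ins", ins, call.category, exp))
        assert mism == []
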