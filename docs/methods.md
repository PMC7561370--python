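# Methods

This note documents the models, parameter choices and known limitations of
the qtlfine pipeline and of the synthetic study it ships with.

## Linkage model

The scan works on an N2 backcross, where every autosomal locus is N/N or
N/D. At a fully genotyped marker, maximum-likelihood interval mapping
reduces to a one-way comparison of the two genotype classes, so the scan is
implemented as single-marker regression:

    LOD = (n/2) · log10(RSS0 / RSS1)

with RSS0 the residual sum of squares about the grand phenotype mean and
RSS1 about the class means. The identity
`LOD = (n/2)·log10(1 + t²/(n−2))` against the pooled two-sample t statistic
is verified to 1e-9 in the tests. No between-marker imputation is performed:
inference at the markers themselves is identical to EM interval mapping
evaluated at marker positions, and the synthetic cohorts are fully
genotyped by construction.

Conventions and edge cases:

* markers need ≥ 2 animals per genotype class, otherwise LOD is NA;
  missing genotypes are dropped marker-wise, not animal-wise;
* a zero-variance phenotype yields LOD 0 everywhere and is flagged;
* the genome-wide threshold is the (1−α) quantile, "higher" interpolation
  (conservative), of the max-LOD distribution over phenotype permutations
  (default 1,000; exhaustive enumeration available for tiny cohorts, where
  the threshold is exactly invariant under relabeling);
* ties between peak markers break toward the lowest genomic coordinate;
* effect sizes use the pooled (Student) two-sample t-test, two-sided, with
  Welch available behind a flag; SEM = sd/√n per group.

Both α = 0.05 and α = 0.01 thresholds are computed by the linkage driver,
since either convention is defensible for a drawn significance line.

## Haplotype windowing

Windows of 250 kb tile the region from its start (no sliding, no overlap;
the final partial window is scored against the same absolute count). A SNP
matches the strain distribution pattern iff every background strain carries
the reference allele and the carrier strain differs from it; any MISSING
call fails the pattern, and indels are excluded from window counts (they
are retained for consequence calling). "Exceeding the threshold of 100
SNPs" is read strictly (> 100); a switch selects ≥. A config switch also
relaxes the pattern to "background strains agree with each other" instead
of "equal the reference". Blocks are maximal runs of consecutive
polymorphic windows.

## Variant consequences

Per overlapping gene, exactly one most-severe category is assigned
(stop_gained > frameshift > missense > splice_region > synonymous >
other_exonic > intron > upstream); a variant touching no gene and no
upstream window is intergenic. Choices:

* upstream means within 5,000 bp of the TSS, strand-aware (the promoter
  scan separately uses 2,000 bp); both are configurable;
* splice_region covers 1–3 bp on the exonic side and 3–8 bp on the
  intronic side of internal exon junctions; the canonical ±1–2 intronic
  dinucleotides are not separated out (the category set has no
  splice_donor/acceptor), so they fall to intron — a deliberate
  simplification;
* indels are attributed to the bases they delete (the VCF anchor base is
  untouched) or to the anchor base for insertions; a CDS-overlapping indel
  whose length change is not a multiple of three is a frameshift;
* coding SNPs are translated with the standard genetic code after
  reverse-complementing for − strand genes; protein changes are numbered
  from the initiator methionine (codon 169 CCA→CTA renders P169L);
* multiallelic VCF sites are decomposed into one record per alternate
  allele; MNPs (equal-length alleles > 1 bp) are rejected.

An exhaustive oracle test reclassifies every possible SNP and 1–3-bp indel
across a five-exon gene on both strands by whole-protein comparison and
per-base interval scanning, and must agree with the classifier everywhere.

## Islet differential expression

Per gene, a pooled-variance two-sided t-test on log2(FPKM+1) (variance
stabilization; raw scale behind a flag) with fold change reported on the
raw scale as (mean_DD + ε)/(mean_NN + ε), ε = 0.01. The module's default
flag is raw p < 0.05; the assembled study screens all measured genes at
once and therefore flags by Benjamini–Hochberg q < 0.05 instead — at ~140
genes, raw-p flagging would admit ≈ 7 false positives per run and make the
candidate list irreproducible across seeds, while BH keeps the planted
genes (fold changes 3–4, cv 0.2, n = 4/group give per-gene p ≈ 1e-4) and
suppresses null genes. Groups with fewer than two samples, all-zero genes
and zero-variance genes give p = NA and are never flagged.

## TFBS scanning

Count matrices become log-odds matrices in bits:
`w[b,i] = log2(((n[b,i] + p·q_b)/(N_i + p))/q_b)` with pseudocount p = 0.8
split by background q (uniform by default). A window's relative score is
`(score − min)/(max − min)`; sites are called at ≥ 0.80, a widespread
convention. The − strand scores the reverse complement; windows containing
N are skipped. For haplotype comparison the alternate sequence is rebuilt
in full (indels shift coordinates) and a matrix is reported only when its
sites pass on exactly one haplotype.

The planted promoter disruption is a 2–4-bp deletion of the site's central
core, not a substitution: a single substitution in a max-scoring site
shifts the score by at most one column's range, which for any reasonably
specific matrix is well under the 20% of the total score range needed to
cross the 0.8 relative threshold — only a span-degenerate (hence
unspecific) matrix could be "destroyed" by one SNP. A central deletion
breaks the site robustly and, because decoy-matrix hits elsewhere merely
shift position, leaves every other matrix's pass/fail status unchanged.
Candidate deletions avoid motif edges (an edge deletion leaves the
remaining columns aligned in a shifted frame) and try lengths 2–4 so that
short tandem repeats inside a core (which realign after a repeat-period
deletion) are still broken.

## The synthetic study

The default scenario fixes the study design; the master seed only moves
noise and placements within it.

* **Geometry.** Initial congenic interval chr4:103.9–117.5 Mbp (13.6 Mbp),
  refined interval 108.1–111.4 Mbp (3.3 Mbp). Three haplotype blocks are
  planted on the 250-kb grid of the refined interval (3 + 2 + 1 windows).
* **Annotation.** 284 gene models in the initial interval: 139 annotated,
  75 predicted gene models, 3 pseudogenes, 67 non-coding RNAs (the three
  pseudogenes are counted among the 78 "gene models" in summaries, since
  the two published category systems — 139/78/67 for the interval versus
  11 annotated/1 model/3 pseudogenes/3 ncRNAs for the blocks — cannot both
  be four-way consistent). The refined interval holds 61 genes, the blocks
  exactly 18. Coding genes get 2–5 exons and a CDS divisible by three.
* **Variants.** Pattern-SNP densities of 400 per window inside blocks and
  20 outside (threshold 100 is straddled by far more than 25%), 150
  non-pattern SNPs per window, 15% additional indels, 2% missing calls.
  Exons of refined-interval genes carry no random strain differences —
  coding sequence is conserved between these closely related strains, and
  the engineered missense (Ttc39a, P169L, pattern B6 = NZO ≠ DBA) and
  1-bp frameshift deletion (first coding exon of Calr4) are the only
  protein-altering variants, mirroring the observed variant spectrum of
  such a region (predominantly intronic/upstream/intergenic).
* **Backcross.** n = 288 animals, 45 markers on four chromosomes (10-Mbp
  spacing), crossovers via the Haldane map at 1 cM/Mbp. Additive effects
  at the chr4 110-Mbp marker are calibrated so the *expected* LOD equals
  8 (blood glucose: +2.98 mM on sd 4.0), 3.7 (plasma insulin: −0.74 ng/ml
  on sd 1.5) and 6 (pancreatic insulin: −12.7 µg on sd 20) at this sample
  size; realized peaks scatter around those values seed by seed.
* **Expression.** FPKM-like lognormal values, cv 0.2, n = 4 per group, for
  the 138 annotated genes detected in islets (Calr4 is not detected — its
  candidacy rests on the frameshift alone). Six genes in the refined
  interval are differentially expressed (folds 3.0 / 0.3 / 0.25 for the
  in-block genes Kti12, Osbpl9, Ttc39a; 4.0 / 0.25 / 3.5 for three genes
  outside blocks).
* **Promoter.** The 2-kb sequence upstream of the Ttc39a TSS carries a
  maximal site for one of ten islet-factor matrices (Foxa2 in the panel of
  Pdx1, Foxa2, Neurod1, Hnf1a, Hnf4a, Mafa, Nkx6-1, Pax6, Isl1, Creb1 —
  synthetic count matrices named after islet transcription factors, not
  database entries), destroyed on the carrier haplotype by the planted
  core deletion.
* **Congenic prevalence.** Blood-glucose groups N/N, N/D, D/D with means
  10.3 / 15.2 / 18.5 mM (sd 4.5) and n = 12 / 16 / 12, chosen so the
  normal tail above the 16.6 mM diabetes cutoff matches prevalences of
  8.3 / 37.5 / 66.6%; with such small groups the realized percentages
  scatter widely, as they do in real cohorts.

What the generator does **not** emulate: linkage disequilibrium structure
within blocks, count-level (negative-binomial) RNA-seq noise, shared-donor
correlation between traits, genotyping error, epistasis, sex and diet
effects. Passing tests therefore demonstrate the correctness and
calibration of the computations, not robustness to those real-data
complications.

## Problem sizes and numerical choices

The test suite and the acceptance script use the study at its native scale
(288 animals, 1,000 permutations, 3.3-Mbp sequence, 284 genes) and scale
calibration experiments to 200 null replicates × 1,000 permutations
(n = 100, 20 markers), 20 localization seeds and 40 expression seeds —
sizes at which the binomial confidence intervals used in the assertions are
meaningful. Permutation scans are vectorized across permutations (one
matrix product per marker block); quantiles use the conservative "higher"
rule; LOD ratios guard RSS1 = 0 with a floor and clamp at zero; seeds are
spawned per stage from one master seed via `SeedSequence`, so every fixture
is byte-reproducible.

## Known limitations

* Single-marker scan only: no interval mapping between markers, no
  covariates, no X-chromosome special-casing, no multi-QTL models.
* The candidate rule treats evidence as boolean; it does not rank
  candidates or weigh effect sizes.
* Biotype mapping from annotation strings is heuristic and user-overridable;
  published gene counts depend on the annotation release and are matched
  here only because the synthetic annotation is constructed to the stated
  composition.
* TFBS scanning uses independent-column PWMs; no dinucleotide dependence,
  DNA shape, or chromatin context.
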