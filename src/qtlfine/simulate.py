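"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: multi-strain
variant tables with planted polymorphic haplotype windows, an N2 backcross
cohort with a planted additive QTL, FPKM-like islet expression with
planted fold changes, gene models with mixed biotypes and CDS structure,
and promoter haplotype pairs with a planted TFBS-disrupting variant.  Each
generator records its truth (what was planted, under which seed) so the
expected output of every downstream stage can be computed by brute force.

All generators are deterministic: the same seed reproduces byte-identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix, GROUP_DD, GROUP_NN
from .genes import ANNOTATED, GENE_MODEL, NONCODING, PSEUDOGENE, GeneModel
from .intervals import GenomicInterval
from .linkage import BackcrossCohort
from .sequences import RegionSequence
from .tfbs import BASES, PWM, pfm_to_pwm, scan_sequence
from .variants import MISSING, StrainPanel, VariantRecord, VariantTable

_OTHER_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class SimulationTruth:
    """What was planted, recorded verbatim alongside every fixture."""

    seed: int
    planted_blocks: list[GenomicInterval] = field(default_factory=list)
    planted_qtl_marker: str | None = None
    additive_effect: float | None = None
    de_genes: dict[str, float] = field(default_factory=dict)
    disrupted_tfs: list[str] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "planted_blocks": [
                {"chrom": b.chrom, "start": b.start, "end": b.end} for b in self.planted_blocks
            ],
            "planted_qtl_marker": self.planted_qtl_marker,
            "additive_effect": self.additive_effect,
            "de_genes": dict(self.de_genes),
            "disrupted_tfs": list(self.disrupted_tfs),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            seed=doc["seed"],
            planted_blocks=[
                GenomicInterval(b["chrom"], b["start"], b["end"]) for b in doc["planted_blocks"]
            ],
            planted_qtl_marker=doc.get("planted_qtl_marker"),
            additive_effect=doc.get("additive_effect"),
            de_genes=doc.get("de_genes") or {},
            disrupted_tfs=doc.get("disrupted_tfs") or [],
        )


# ---------------------------------------------------------------------------
# strain variant tables with planted polymorphic windows


def _pattern_calls(panel: StrainPanel, ref: str, alt: str) -> dict[str, str]:
    calls = {s: ref for s in panel.background_strains}
    calls[panel.carrier_strain] = alt
    return calls


def _nonpattern_calls(panel: StrainPanel, ref: str, alt: str, rng) -> dict[str, str]:
    """Calls violating the pattern: a background strain joins the carrier,
    or all strains stay on the reference allele."""
    calls = {s: ref for s in panel.background_strains}
    calls[panel.carrier_strain] = ref
    if panel.background_strains and rng.random() < 0.5:
        calls[rng.choice(list(panel.background_strains))] = alt
        calls[panel.carrier_strain] = alt
    return calls


def simulate_strain_variants(
    region: GenomicInterval,
    panel: StrainPanel,
    n_blocks: int,
    block_len: int,
    in_block_density: float,
    out_block_density: float,
    missing_rate: float = 0.0,
    nonpattern_density: float = 100.0,
    indel_fraction: float = 0.1,
    window_size: int = 250_000,
    seed: int = 0,
    planted_blocks: list[GenomicInterval] | None = None,
    sequence: RegionSequence | None = None,
    exclude: list[GenomicInterval] | None = None,
) -> tuple[VariantTable, SimulationTruth]:
    """Plant carrier-specific SNP clusters on a window grid.

    Densities are SNPs per 250-kb window.  Planted blocks are aligned to
    the window grid (anchored at the region start) and separated by at
    least one non-block window, so windowed recovery is well defined.
    Per-window pattern-SNP counts are deterministic (density scaled by
    window length); positions, non-pattern calls and missingness are drawn
    from the seeded generator.  ``planted_blocks`` overrides random block
    placement with explicit grid-aligned intervals.
    """
    if block_len > len(region):
        raise ValueError("block_len exceeds region length")
    rng = np.random.default_rng(seed)
    n_windows = (len(region) + window_size - 1) // window_size
    win_per_block = max(1, int(round(block_len / window_size)))
    if planted_blocks is None and n_blocks * (win_per_block + 1) > n_windows + 1:
        raise ValueError("planted blocks do not fit in the region")

    block_windows: set[int] = set()
    if planted_blocks is not None:
        planted = list(planted_blocks)
        for b in planted:
            if (b.start - region.start) % window_size:
                raise ValueError(f"block {b} not aligned to the window grid")
            first = (b.start - region.start) // window_size
            n_win = (len(b) + window_size - 1) // window_size
            block_windows |= set(range(first, first + n_win))
    else:
        starts: list[int] = []
        attempts = 0
        while len(starts) < n_blocks:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("could not place non-adjacent blocks")
            s = int(rng.integers(0, n_windows - win_per_block + 1))
            span = set(range(s - 1, s + win_per_block + 1))  # 1-window buffer
            if span & block_windows:
                continue
            starts.append(s)
            block_windows |= set(range(s, s + win_per_block))
        starts.sort()
        planted = [
            GenomicInterval(
                region.chrom,
                region.start + s * window_size,
                min(region.start + (s + win_per_block) * window_size, region.end),
            )
            for s in starts
        ]

    records: list[VariantRecord] = []
    used_positions: set[int] = set()
    excluded = list(exclude or [])

    def draw_positions(wstart: int, wend: int, k: int) -> np.ndarray:
        k = min(k, wend - wstart)
        pool = rng.choice(wend - wstart, size=min((wend - wstart), 4 * k + 16), replace=False)
        out = []
        for off in pool:
            p = wstart + int(off)
            if p in used_positions:
                continue
            if any(iv.contains(region.chrom, p) for iv in excluded):
                continue
            used_positions.add(p)
            out.append(p)
            if len(out) == k:
                break
        return np.array(sorted(out), dtype=int)

    def add_snp(pos0: int, pattern: bool) -> None:
        ref = sequence.base_at(pos0) if sequence is not None else rng.choice(list(BASES))
        alt = _OTHER_BASE[ref]
        calls = (
            _pattern_calls(panel, ref, alt)
            if pattern
            else _nonpattern_calls(panel, ref, alt, rng)
        )
        if missing_rate > 0:
            calls = {
                s: (MISSING if rng.random() < missing_rate else a) for s, a in calls.items()
            }
        records.append(VariantRecord(region.chrom, pos0 + 1, ref, alt, calls))

    def add_indel(pos0: int) -> None:
        ins = rng.random() < 0.5
        tail_len = int(rng.integers(1, 4))
        if sequence is not None and pos0 + 1 + tail_len <= sequence.end0:
            ref = sequence.base_at(pos0)
            genomic_tail = sequence.slice(pos0 + 1, pos0 + 1 + tail_len)
        else:
            ref = rng.choice(list(BASES))
            genomic_tail = None
        tail = "".join(rng.choice(list(BASES), size=tail_len))
        if ins:
            r, a = ref, ref + tail
        else:
            r, a = ref + (genomic_tail or tail), ref
        records.append(
            VariantRecord(region.chrom, pos0 + 1, r, a, _pattern_calls(panel, r, a))
        )

    for w in range(n_windows):
        wstart = region.start + w * window_size
        wend = min(wstart + window_size, region.end)
        frac = (wend - wstart) / window_size
        density = in_block_density if w in block_windows else out_block_density
        n_pattern = int(round(density * frac))
        n_non = int(round(nonpattern_density * frac))
        n_ind = int(round(indel_fraction * (n_pattern + n_non)))
        for p in draw_positions(wstart, wend, n_pattern):
            add_snp(int(p), pattern=True)
        for p in draw_positions(wstart, wend, n_non):
            add_snp(int(p), pattern=False)
        for p in draw_positions(wstart, wend, n_ind):
            add_indel(int(p))

    truth = SimulationTruth(seed=seed, planted_blocks=planted)
    return VariantTable(records, panel), truth


# ---------------------------------------------------------------------------
# backcross cohort with a planted additive QTL


def haldane_recomb_fraction(distance_bp: float, cm_per_mbp: float = 1.0) -> float:
    """Recombination fraction from physical distance via the Haldane map
    (default mouse heuristic 1 cM per Mbp)."""
    morgans = distance_bp / 1e6 * cm_per_mbp / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def simulate_backcross(
    n_individuals: int,
    marker_map: list[tuple[str, str, int]],
    qtl_marker: str,
    additive_effect: float,
    residual_sd: float,
    seed: int = 0,
    baseline: float = 0.0,
    phenotype_name: str = "phenotype",
    traits: dict[str, tuple[float, float, float]] | None = None,
    cm_per_mbp: float = 1.0,
) -> tuple[BackcrossCohort, SimulationTruth]:
    """N2 backcross: each marker is N/N or N/D (expected 1:1), with linked
    markers inheriting through Haldane crossovers.

    phenotype = baseline + effect * I(N/D at the QTL marker) + N(0, sd).
    ``traits`` may name several phenotypes as {name: (baseline, effect, sd)};
    otherwise a single ``phenotype_name`` trait uses the scalar arguments.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    marker_ids = [m[0] for m in marker_map]
    if qtl_marker not in marker_ids:
        raise ValueError(f"qtl_marker {qtl_marker!r} not in marker map")
    rng = np.random.default_rng(seed)

    geno = np.zeros((n_individuals, len(marker_map)), dtype=np.int8)
    start = 0
    while start < len(marker_map):
        chrom = marker_map[start][1]
        end = start
        while end < len(marker_map) and marker_map[end][1] == chrom:
            end += 1
        geno[:, start] = rng.integers(0, 2, size=n_individuals)
        for j in range(start + 1, end):
            r = haldane_recomb_fraction(marker_map[j][2] - marker_map[j - 1][2], cm_per_mbp)
            flip = rng.random(n_individuals) < r
            geno[:, j] = np.where(flip, 1 - geno[:, j - 1], geno[:, j - 1])
        start = end

    q = marker_ids.index(qtl_marker)
    trait_spec = traits or {phenotype_name: (baseline, additive_effect, residual_sd)}
    phenotypes = {
        name: base + eff * geno[:, q] + rng.normal(0.0, sd, size=n_individuals)
        for name, (base, eff, sd) in trait_spec.items()
    }
    cohort = BackcrossCohort(
        individuals=[f"ind{i + 1:04d}" for i in range(n_individuals)],
        markers=list(marker_map),
        genotypes=geno,
        phenotypes=phenotypes,
    )
    truth = SimulationTruth(
        seed=seed, planted_qtl_marker=qtl_marker, additive_effect=additive_effect
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# expression matrix with planted fold changes


def simulate_expression(
    gene_list: list[str],
    n_per_group: int = 4,
    de_map: dict[str, float] | None = None,
    base_level: float = 10.0,
    cv: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """FPKM-like two-group matrix with lognormal noise.

    The D/D group mean of a DE gene is shifted by its fold change; noise is
    lognormal with the requested coefficient of variation around the group
    mean, so values stay non-negative.  n = 4 per group by default.
    """
    de_map = de_map or {}
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    samples = [f"NN_{i + 1}" for i in range(n_per_group)] + [
        f"DD_{i + 1}" for i in range(n_per_group)
    ]
    groups = {s: (GROUP_NN if s.startswith("NN") else GROUP_DD) for s in samples}
    data = np.empty((len(gene_list), 2 * n_per_group))
    for gi, gene in enumerate(gene_list):
        fc = de_map.get(gene, 1.0)
        means = np.array([base_level] * n_per_group + [base_level * fc] * n_per_group)
        z = rng.normal(size=2 * n_per_group)
        data[gi] = means * np.exp(sigma * z - sigma**2 / 2.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=pd.Index(gene_list, name="gene"), columns=samples), groups
    )
    return matrix, SimulationTruth(seed=seed, de_genes=dict(de_map))


# ---------------------------------------------------------------------------
# gene models with mixed biotypes


def _coding_structure(
    rng, gstart: int, gend: int, chrom: str, n_exons: int
) -> tuple[list[GenomicInterval], list[tuple[GenomicInterval, int]]]:
    """Exons tiling part of [gstart, gend) and a CDS with total length % 3 == 0."""
    length = gend - gstart
    bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 1, replace=False))
    cuts = [0, *map(int, bounds), length]
    exons = [
        GenomicInterval(chrom, gstart + cuts[2 * i], gstart + cuts[2 * i + 1])
        for i in range(n_exons)
    ]
    # CDS: trim the outermost exons to leave UTRs, then fix total length % 3
    cds_iv = [GenomicInterval(e.chrom, e.start, e.end) for e in exons]
    utr5 = min(len(cds_iv[0]) - 1, int(rng.integers(0, max(1, len(cds_iv[0]) // 3))))
    utr3 = min(len(cds_iv[-1]) - 1, int(rng.integers(0, max(1, len(cds_iv[-1]) // 3))))
    cds_iv[0] = GenomicInterval(chrom, cds_iv[0].start + utr5, cds_iv[0].end)
    cds_iv[-1] = GenomicInterval(chrom, cds_iv[-1].start, cds_iv[-1].end - utr3)
    total = sum(len(c) for c in cds_iv)
    trim = total % 3
    if trim:
        last = cds_iv[-1]
        if len(last) > trim:
            cds_iv[-1] = GenomicInterval(chrom, last.start, last.end - trim)
        else:
            first = cds_iv[0]
            cds_iv[0] = GenomicInterval(chrom, first.start + trim, first.end)
    cds = []
    consumed = 0
    for c in cds_iv:  # phases in genomic order, assuming + strand ordering
        cds.append((c, (3 - consumed % 3) % 3))
        consumed += len(c)
    return exons, cds


def _phases_for_strand(cds_iv: list[GenomicInterval], strand: str) -> list[tuple[GenomicInterval, int]]:
    ordered = cds_iv if strand == "+" else list(reversed(cds_iv))
    out = []
    consumed = 0
    for c in ordered:
        out.append((c, (3 - consumed % 3) % 3))
        consumed += len(c)
    return sorted(out, key=lambda t: t[0].start)


def simulate_gene_models(
    interval: GenomicInterval,
    composition: dict[str, int],
    seed: int = 0,
    mean_gene_len: int = 8_000,
    named_genes: dict[str, tuple[str, int]] | None = None,
    id_prefix: str = "",
) -> list[GeneModel]:
    """Non-overlapping gene models with the requested biotype composition.

    Genes are placed in equal slots across the interval with jitter;
    protein-coding genes receive 2-5 exons and a CDS whose total length is
    a multiple of three.  ``named_genes`` pins specific genes to positions:
    {name: (biotype, start0)} — these consume slots nearest their position
    and their own biotype's share of the composition.  ``id_prefix``
    namespaces the generated identifiers when several calls tile a region.
    """
    rng = np.random.default_rng(seed)
    named = dict(named_genes or {})
    biotypes: list[str] = []
    for bt in (ANNOTATED, GENE_MODEL, PSEUDOGENE, NONCODING):
        biotypes += [bt] * composition.get(bt, 0)
    # named genes consume a slot of their own biotype, keeping the composition
    for name, (bt, _start0) in named.items():
        try:
            biotypes.remove(bt)
        except ValueError:
            raise ValueError(f"named gene {name!r}: no {bt} left in composition") from None
    rng.shuffle(biotypes)
    n = len(biotypes) + len(named)
    slot = len(interval) // max(n, 1)
    if slot < 600:
        raise ValueError("interval too small for the requested gene count")

    named_slots: dict[int, tuple[str, str]] = {}
    for name, (bt, start0) in named.items():
        idx = min(n - 1, max(0, (start0 - interval.start) // slot))
        while idx in named_slots:
            idx += 1
        named_slots[idx] = (name, bt)

    genes: list[GeneModel] = []
    counters = {ANNOTATED: 0, GENE_MODEL: 0, PSEUDOGENE: 0, NONCODING: 0}
    prefix = {ANNOTATED: "Gene", GENE_MODEL: "Gm", PSEUDOGENE: "Ps", NONCODING: "Nc"}
    bi = 0
    for i in range(n):
        if i in named_slots:
            name, bt = named_slots[i]
        else:
            bt = biotypes[bi]
            bi += 1
            counters[bt] += 1
            name = f"{id_prefix}{prefix[bt]}{counters[bt]:04d}"
        slot_start = interval.start + i * slot
        glen = int(np.clip(rng.normal(mean_gene_len, mean_gene_len / 3), 500, slot - 100))
        gstart = slot_start + int(rng.integers(0, max(1, slot - glen)))
        gend = gstart + glen
        strand = "+" if rng.random() < 0.5 else "-"
        if bt == ANNOTATED:
            n_exons = int(rng.integers(2, 6))
            exons, cds = _coding_structure(rng, gstart, gend, interval.chrom, n_exons)
            cds = _phases_for_strand([c for c, _ in cds], strand)
        else:
            n_exons = int(rng.integers(1, 4))
            exons, _ = _coding_structure(rng, gstart, gend, interval.chrom, n_exons)
            cds = []
        genes.append(
            GeneModel(
                gene_id=name,
                gene_name=name,
                biotype=bt,
                interval=GenomicInterval(interval.chrom, gstart, gend),
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# region sequence


def simulate_region_sequence(region: GenomicInterval, seed: int = 0) -> RegionSequence:
    """Uniform-random genomic sequence for the region."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=len(region))])
    return RegionSequence(region.chrom, region.start, seq)


# ---------------------------------------------------------------------------
# promoter haplotype pair with a planted TFBS-disrupting variant


@dataclass
class PromoterPair:
    ref_seq: str
    variant: VariantRecord
    pwm: PWM
    site_pos: int  # 1-based on the promoter sequence
    truth: SimulationTruth


def _candidate_deletions(pwm: PWM) -> list[tuple[int, int]]:
    """(offset, length) candidates for a site-disrupting core deletion.

    Central offsets are tried first (an edge deletion leaves the rest of
    the site aligned in a shifted frame) with lengths 2-4; longer
    deletions break motifs whose core contains a short tandem repeat,
    which realigns after a repeat-period deletion.
    """
    lo = max(1, pwm.length // 3)
    hi = max(lo + 1, 2 * pwm.length // 3)
    center = (lo + hi) // 2
    offsets = sorted(range(lo, hi), key=lambda o: abs(o - center))
    return [(off, dlen) for dlen in (2, 3, 4) for off in offsets]


def simulate_promoter_pair(
    pwm: PWM,
    length: int = 2000,
    site_pos: int | None = None,
    seed: int = 0,
    rel_threshold: float = 0.80,
    chrom: str = "chr4",
    origin_pos: int = 1,
    decoys: list[PWM] | None = None,
    max_attempts: int = 50,
) -> PromoterPair:
    """Promoter whose reference haplotype carries a maximal PWM site that a
    planted core deletion destroys.

    The reference sequence carries the PWM consensus at ``site_pos``; the
    planted carrier-specific variant deletes the two most informative core
    bases, so the site's relative score falls far below the threshold on
    the alternate haplotype (a single substitution cannot take a
    max-scoring site below 0.8 relative score for any reasonably specific
    matrix, because one column contributes only a small share of the score
    range).  The random background is verified (and redrawn if needed) so
    that the alternate haplotype carries no passing site for the planted
    PWM, and no decoy PWM changes status between haplotypes.
    """
    # stream decoupled from any generator that consumed the bare seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70]))
    decoys = decoys or []
    L = pwm.length
    if site_pos is None:
        site_pos = length // 2
    if not 1 <= site_pos <= length - L + 1:
        raise ValueError("site_pos outside the promoter")
    consensus = pwm.consensus
    for _ in range(max_attempts):
        seq = list("".join(np.array(list(BASES))[rng.integers(0, 4, size=length)]))
        seq[site_pos - 1 : site_pos - 1 + L] = list(consensus)
        ref_seq = "".join(seq)
        if not scan_sequence(pwm, ref_seq, rel_threshold):
            continue
        for core, dlen in _candidate_deletions(pwm):
            # deletion anchored one base before the removed core bases
            anchor = site_pos + core - 1  # 1-based; core offset is 0-based
            ref_allele = ref_seq[anchor - 1 : anchor + dlen]
            alt_allele = ref_allele[0]
            alt_seq = ref_seq[:anchor] + ref_seq[anchor + dlen :]
            if scan_sequence(pwm, alt_seq, rel_threshold):
                continue
            decoy_ok = all(
                bool(scan_sequence(d, ref_seq, rel_threshold))
                == bool(scan_sequence(d, alt_seq, rel_threshold))
                for d in decoys
            )
            if not decoy_ok:
                continue
            variant = VariantRecord(
                chrom,
                origin_pos + anchor - 1,
                ref_allele,
                alt_allele,
                strain_calls={},
            )
            truth = SimulationTruth(seed=seed, disrupted_tfs=[pwm.name])
            return PromoterPair(ref_seq, variant, pwm, site_pos, truth)
    raise RuntimeError("could not construct a clean promoter pair; try another seed")


def random_pfm(rng, length: int = 12, total: int = 20) -> np.ndarray:
    """An informative random count matrix (one dominant base per column)."""
    counts = np.zeros((4, length))
    for j in range(length):
        dominant = int(rng.integers(0, 4))
        counts[dominant, j] = total - 3
        for b in range(4):
            if b != dominant:
                counts[b, j] = 1
    return counts


def make_pfm_panel(
    n: int, seed: int = 0, length: int = 12, names: list[str] | None = None
) -> list[tuple[str, np.ndarray]]:
    """Named random count matrices (the on-disk JASPAR-style panel)."""
    rng = np.random.default_rng(seed)
    return [
        (names[i] if names else f"TF{i + 1:02d}", random_pfm(rng, length=length))
        for i in range(n)
    ]


def make_pwm_set(n: int, seed: int = 0, length: int = 12, names: list[str] | None = None) -> list[PWM]:
    """A panel of informative PWMs built from random count matrices."""
    return [
        pfm_to_pwm(counts, name=name)
        for name, counts in make_pfm_panel(n, seed=seed, length=length, names=names)
    ]


# ---------------------------------------------------------------------------
# congenic blood-glucose groups (diabetes prevalence)


def simulate_congenic_glucose(
    group_means: dict[str, float],
    sd: float,
    n_per_group: dict[str, int],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Blood-glucose vectors (mM) for congenic genotype groups."""
    rng = np.random.default_rng(seed)
    return {
        grp: rng.normal(group_means[grp], sd, size=n_per_group[grp])
        for grp in group_means
    }
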