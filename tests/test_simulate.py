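import numpy as np
import pytest

from qtlfine.genes import ANNOTATED, GENE_MODEL, NONCODING, PSEUDOGENE
from qtlfine.haploblocks import pattern_match, window_scan
from qtlfine.intervals import GenomicInterval
from qtlfine.linkage import lod_scan, peak_marker
from qtlfine.simulate import (
    SimulationTruth,
    make_pwm_set,
    simulate_backcross,
    simulate_expression,
    simulate_gene_models,
    simulate_promoter_pair,
    simulate_strain_variants,
)
from qtlfine.tfbs import delta_sites, scan_sequence

REGION = GenomicInterval("chr4", 20_000_000, 24_000_000)


class TestStrainVariants:
    def test_identical_seeds_identical_fixtures(self, panel):
        kw = dict(n_blocks=2, block_len=500_000, in_block_density=150,
                  out_block_density=30, missing_rate=0.05, seed=11)
        t1, tr1 = simulate_strain_variants(REGION, panel, **kw)
        t2, tr2 = simulate_strain_variants(REGION, panel, **kw)
        assert [
            (r.pos, r.ref_allele, r.alt_allele, tuple(sorted(r.strain_calls.items())))
            for r in t1
        ] == [
            (r.pos, r.ref_allele, r.alt_allele, tuple(sorted(r.strain_calls.items())))
            for r in t2
        ]
        assert tr1.planted_blocks == tr2.planted_blocks

    def test_no_blocks_no_window_exceeds_threshold(self, panel):
        table, _ = simulate_strain_variants(
            REGION, panel, n_blocks=0, block_len=250_000,
            in_block_density=150, out_block_density=30, seed=3,
        )
        assert not any(w.polymorphic for w in window_scan(table, REGION, panel))

    def test_full_missingness_kills_every_pattern(self, panel):
        table, _ = simulate_strain_variants(
            REGION, panel, n_blocks=1, block_len=500_000,
            in_block_density=200, out_block_density=30,
            missing_rate=1.0, seed=4,
        )
        assert not any(pattern_match(r, panel) for r in table if r.is_snp)

    def test_oversized_block_fatal(self, panel):
        with pytest.raises(ValueError):
            simulate_strain_variants(
                REGION, panel, n_blocks=1, block_len=5_000_000,
                in_block_density=150, out_block_density=30, seed=0,
            )

    def test_window_scan_flags_exactly_covering_windows(self, panel):
        table, truth = simulate_strain_variants(
            REGION, panel, n_blocks=1, block_len=500_000,
            in_block_density=150, out_block_density=20, seed=5,
        )
        windows = window_scan(table, REGION, panel)
        flagged = [w.interval for w in windows if w.polymorphic]
        (block,) = truth.planted_blocks
        covering = [w.interval for w in windows if w.interval.overlaps(block)]
        assert flagged == covering


class TestBackcross:
    MAP = [(f"m{j}", "chr1", (10 + 10 * j) * 1_000_000) for j in range(10)]

    def test_zero_individuals_fatal(self):
        with pytest.raises(ValueError):
            simulate_backcross(0, self.MAP, "m0", 1.0, 1.0, seed=0)

    def test_unknown_qtl_marker_fatal(self):
        with pytest.raises(ValueError):
            simulate_backcross(10, self.MAP, "nope", 1.0, 1.0, seed=0)

    def test_genotype_ratio_near_one_to_one(self):
        cohort, _ = simulate_backcross(2000, self.MAP, "m5", 0.0, 1.0, seed=9)
        frac = cohort.genotypes.mean()
        assert 0.47 < frac < 0.53

    def test_linked_markers_correlate_by_map_distance(self):
        cohort, _ = simulate_backcross(4000, self.MAP, "m5", 0.0, 1.0, seed=10)
        g = cohort.genotypes
        r_adjacent = np.mean(g[:, 0] != g[:, 1])  # 10 Mbp ~ 10 cM apart
        r_far = np.mean(g[:, 0] != g[:, 9])
        assert 0.05 < r_adjacent < 0.14
        assert r_far > 0.3

    def test_planted_qtl_localized_across_seeds(self):
        """Effect 2*sd at n=200: the peak marker is the planted one in >=90%
        of seeded replicates (oracle: repeated simulation)."""
        hits = 0
        for seed in range(20):
            cohort, truth = simulate_backcross(
                200, self.MAP, "m5", additive_effect=2.0, residual_sd=1.0, seed=seed
            )
            res = lod_scan(cohort, "phenotype")
            hits += peak_marker(res, cohort) == truth.planted_qtl_marker
        assert hits >= 18

    def test_phenotype_model(self):
        cohort, _ = simulate_backcross(
            5000, self.MAP, "m0", additive_effect=3.0, residual_sd=0.5,
            baseline=10.0, seed=2,
        )
        y = cohort.phenotypes["phenotype"]
        g = cohort.genotypes[:, 0]
        assert np.mean(y[g == 0]) == pytest.approx(10.0, abs=0.1)
        assert np.mean(y[g == 1]) == pytest.approx(13.0, abs=0.1)


class TestExpressionSim:
    def test_group_structure_and_nonnegativity(self):
        m, truth = simulate_expression(["a", "b"], n_per_group=4, de_map={"b": 4.0}, seed=0)
        assert m.values.shape == (2, 8)
        assert (m.values.to_numpy() >= 0).all()
        assert truth.de_genes == {"b": 4.0}

    def test_fold_change_on_the_mean(self):
        m, _ = simulate_expression(
            ["g"], n_per_group=2000, de_map={"g": 4.0}, base_level=10.0, cv=0.2, seed=1
        )
        nn = m.values.loc["g", m.samples_of("NN")].mean()
        dd = m.values.loc["g", m.samples_of("DD")].mean()
        assert dd / nn == pytest.approx(4.0, rel=0.05)

    def test_single_sample_group_p_undefined(self):
        from qtlfine.expression import differential_expression

        m, _ = simulate_expression(["g"], n_per_group=1, seed=0)
        with pytest.warns(UserWarning):
            (res,) = differential_expression(m)
        assert np.isnan(res.p_value) and not res.de_flag


class TestGeneModelSim:
    def test_composition_and_disjointness(self):
        comp = {ANNOTATED: 10, GENE_MODEL: 5, PSEUDOGENE: 2, NONCODING: 3}
        genes = simulate_gene_models(GenomicInterval("chr4", 0, 2_000_000), comp, seed=0)
        from collections import Counter

        assert Counter(g.biotype for g in genes) == Counter(comp)
        ordered = sorted(genes, key=lambda g: g.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.interval.end <= b.interval.start

    def test_coding_genes_have_triplet_cds(self):
        genes = simulate_gene_models(
            GenomicInterval("chr4", 0, 1_000_000), {ANNOTATED: 8}, seed=1
        )
        for g in genes:
            assert g.cds and g.cds_length() % 3 == 0

    def test_named_gene_pinned_with_biotype_preserved(self):
        comp = {ANNOTATED: 3, NONCODING: 2}
        genes = simulate_gene_models(
            GenomicInterval("chr4", 0, 1_000_000), comp, seed=2,
            named_genes={"Kti12": (ANNOTATED, 500_000)},
        )
        from collections import Counter

        assert Counter(g.biotype for g in genes) == Counter(comp)
        (kti,) = [g for g in genes if g.gene_id == "Kti12"]
        assert kti.biotype == ANNOTATED


class TestPromoterPair:
    def test_planted_disruption_and_no_false_pwms(self):
        pwms = make_pwm_set(10, seed=21)
        pair = simulate_promoter_pair(
            pwms[0], seed=21, decoys=pwms[1:], origin_pos=1_000_001
        )
        from qtlfine.tfbs import apply_variants

        alt, _ = apply_variants(pair.ref_seq, [pair.variant], origin_pos=1_000_001)
        deltas = delta_sites(pwms, pair.ref_seq, alt)
        assert [(d.pwm_name, d.status) for d in deltas] == [(pwms[0].name, "lost_in_alt")]

    def test_no_variant_no_delta(self):
        pwms = make_pwm_set(3, seed=5)
        pair = simulate_promoter_pair(pwms[0], seed=5, decoys=pwms[1:])
        assert delta_sites(pwms, pair.ref_seq, pair.ref_seq) == []

    def test_reference_site_is_maximal(self):
        pwms = make_pwm_set(1, seed=8)
        pair = simulate_promoter_pair(pwms[0], seed=8)
        hits = scan_sequence(pwms[0], pair.ref_seq, 0.99)
        assert any(h.position == pair.site_pos and h.relative_score == 1.0 for h in hits)


class TestTruthSidecar:
    def test_yaml_round_trip(self, tmp_path):
        truth = SimulationTruth(
            seed=7,
            planted_blocks=[GenomicInterval("chr4", 0, 250_000)],
            planted_qtl_marker="m5",
            additive_effect=2.0,
            de_genes={"Ttc39a": 0.25},
            disrupted_tfs=["Foxa2"],
        )
        p = tmp_path / "truth.yaml"
        truth.to_yaml(p)
        assert SimulationTruth.from_yaml(p) == truth
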