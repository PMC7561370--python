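import numpy as np
import pytest

from qtlfine.sequences import revcomp
from qtlfine.simulate import make_pwm_set, random_pfm
from qtlfine.tfbs import (
    BASES,
    apply_variants,
    delta_sites,
    pfm_to_pwm,
    read_jaspar_pfms,
    scan_sequence,
    write_jaspar_pfms,
)
from qtlfine.variants import VariantRecord


def var(pos, ref, alt):
    return VariantRecord("chr4", pos, ref, alt, {})


class TestPfmToPwm:
    def test_uniform_counts_give_zero_matrix(self):
        pwm = pfm_to_pwm(np.full((4, 5), 3.0), pseudocount=0.0)
        assert np.allclose(pwm.matrix, 0.0)

    def test_single_base_column_two_bits(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 1.0  # A only, pseudocount 0, uniform background
        pwm = pfm_to_pwm(counts, pseudocount=0.0)
        assert pwm.matrix[0, 0] == pytest.approx(2.0)

    def test_zero_column_without_pseudocount_fatal(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(np.zeros((4, 2)), pseudocount=0.0)

    def test_matches_biopython_log_odds(self):
        """Cross-check the log-odds matrix against Bio.motifs with the same
        background-split pseudocount convention."""
        from Bio import motifs
        from Bio.Seq import Seq

        counts = random_pfm(np.random.default_rng(3), length=6)
        pwm = pfm_to_pwm(counts, pseudocount=0.8)
        m = motifs.Motif(
            alignment=None,
            counts={b: list(counts[i]) for i, b in enumerate(BASES)},
        )
        pssm = m.counts.normalize(pseudocounts={b: 0.8 * 0.25 for b in BASES}).log_odds(
            {b: 0.25 for b in BASES}
        )
        for i, b in enumerate(BASES):
            assert np.allclose(pwm.matrix[i], pssm[b], atol=1e-12)

    def test_relative_score_bounds(self):
        pwm = pfm_to_pwm(random_pfm(np.random.default_rng(0)))
        assert pwm.relative(pwm.max_score) == pytest.approx(1.0)
        assert pwm.relative(pwm.min_score) == pytest.approx(0.0)


class TestJasparIO:
    def test_round_trip(self, tmp_path):
        entries = [("Foxa2", random_pfm(np.random.default_rng(1))),
                   ("Pdx1", random_pfm(np.random.default_rng(2)))]
        p = tmp_path / "pfm.txt"
        write_jaspar_pfms(entries, p)
        back = read_jaspar_pfms(p)
        assert [n for n, _ in back] == ["Foxa2", "Pdx1"]
        for (_, a), (_, b) in zip(entries, back):
            assert np.array_equal(a, b)


class TestScanSequence:
    def test_consensus_hits_with_full_relative_score(self):
        pwm = pfm_to_pwm(random_pfm(np.random.default_rng(4)))
        hits = scan_sequence(pwm, pwm.consensus, rel_threshold=0.99)
        assert any(h.position == 1 and h.strand == "+" and h.relative_score == 1.0 for h in hits)

    def test_strand_symmetry(self, rng):
        """Forward score of any window equals the reverse-complement's
        minus-strand score, for every PWM/sequence pair tested."""
        for seed in range(5):
            pwm = pfm_to_pwm(random_pfm(np.random.default_rng(seed)))
            seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=60)])
            fwd = scan_sequence(pwm, seq, rel_threshold=0.0)
            rev = scan_sequence(pwm, revcomp(seq), rel_threshold=0.0)
            f = {(h.position, h.strand): h.score for h in fwd}
            r = {(h.position, h.strand): h.score for h in rev}
            n, L = len(seq), pwm.length
            for (pos, strand), score in f.items():
                mirror = (n - L - (pos - 1) + 1, {"+": "-", "-": "+"}[strand])
                assert score == pytest.approx(r[mirror], abs=1e-9)

    def test_windows_with_n_skipped(self):
        pwm = pfm_to_pwm(random_pfm(np.random.default_rng(6)))
        seq = pwm.consensus[:3] + "N" + pwm.consensus[4:]
        assert scan_sequence(pwm, seq, rel_threshold=0.0) == []

    def test_brute_force_oracle_on_random_sequence(self, rng):
        """The scan equals exhaustive rescoring of every window x strand."""
        pwm = pfm_to_pwm(random_pfm(np.random.default_rng(7)))
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=2000)])
        got = {
            (h.position, h.strand): (h.score, h.relative_score)
            for h in scan_sequence(pwm, seq, rel_threshold=0.8)
        }
        expected = {}
        L = pwm.length
        idx = {b: i for i, b in enumerate(BASES)}
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            for strand, w in (("+", window), ("-", revcomp(window))):
                score = sum(pwm.matrix[idx[b], j] for j, b in enumerate(w))
                rel = (score - pwm.min_score) / (pwm.max_score - pwm.min_score)
                if rel >= 0.8:
                    expected[(start + 1, strand)] = (score, rel)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k][0] == pytest.approx(expected[k][0], abs=1e-9)


class TestApplyVariants:
    def test_no_variants_identity(self):
        seq = "ACGTACGT"
        alt, cmap = apply_variants(seq, [], origin_pos=1)
        assert alt == seq and cmap == list(range(8))

    def test_single_snp_one_position_differs(self):
        seq = "ACGTACGT"
        alt, _ = apply_variants(seq, [var(3, "G", "C")], origin_pos=1)
        assert alt == "ACCTACGT"
        assert sum(a != b for a, b in zip(seq, alt)) == 1

    def test_deletion_shortens_and_maps(self):
        seq = "ACGTACGT"
        alt, cmap = apply_variants(seq, [var(2, "CGT", "C")], origin_pos=1)
        assert alt == "ACACGT" and len(alt) == len(seq) - 2
        assert cmap == [0, 1, 4, 5, 6, 7]

    def test_insertion_maps_new_bases_to_none(self):
        seq = "ACGT"
        alt, cmap = apply_variants(seq, [var(2, "C", "CTT")], origin_pos=1)
        assert alt == "ACTTGT"
        assert cmap == [0, 1, None, None, 2, 3]

    def test_reference_mismatch_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_variants("ACGT", [var(2, "G", "A")], origin_pos=1)

    def test_overlapping_variants_fatal(self):
        with pytest.raises(ValueError, match="verlapping"):
            apply_variants("ACGTAC", [var(2, "CG", "C"), var(3, "G", "A")], origin_pos=1)

    def test_outside_sequence_fatal(self):
        with pytest.raises(ValueError, match="outside"):
            apply_variants("ACGT", [var(10, "A", "G")], origin_pos=1)


class TestDeltaSites:
    def test_identical_sequences_no_deltas(self):
        pwms = make_pwm_set(3, seed=1)
        seq = "".join(np.array(list(BASES))[np.random.default_rng(0).integers(0, 4, 500)])
        assert delta_sites(pwms, seq, seq) == []

    def test_antisymmetry_lost_gained(self):
        """Swapping ref/alt swaps lost_in_alt <-> gained_in_alt."""
        pwms = make_pwm_set(5, seed=2)
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 500)])
        ref = seq[:200] + pwms[0].consensus + seq[200:]
        alt = seq  # site absent
        fwd = {(d.pwm_name, d.status) for d in delta_sites(pwms, ref, alt)}
        rev = {(d.pwm_name, d.status) for d in delta_sites(pwms, alt, ref)}
        swap = {"lost_in_alt": "gained_in_alt", "gained_in_alt": "lost_in_alt"}
        assert {(n, swap[s]) for n, s in fwd} == rev

    def test_gained_consensus_reported(self):
        pwms = make_pwm_set(2, seed=4)
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 300)])
        alt = seq[:100] + pwms[1].consensus + seq[100 + pwms[1].length:]
        deltas = delta_sites([pwms[1]], seq, alt)
        if scan_sequence(pwms[1], seq, 0.8):  # spurious ref hit: no delta
            assert deltas == []
        else:
            assert [(d.pwm_name, d.status) for d in deltas] == [(pwms[1].name, "gained_in_alt")]
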