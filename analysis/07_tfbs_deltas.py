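"""Allele-aware TFBS scan of the Ttc39a promoter.

Builds the DBA promoter haplotype by applying the carrier-specific
variants to the reference 2-kb upstream sequence, scans both haplotypes
with the 10-matrix PWM panel at relative score >= 0.8, and reports
binding sites lost or gained on the DBA haplotype.
"""

import argparse
from pathlib import Path

from qtlfine import tfbs
from qtlfine.pipeline import build_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--rel-threshold", type=float, default=0.80)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    data = build_study(seed=args.seed)
    carrier = data.panel.carrier_strain
    promoter_vars = [
        v for v in data.variants
        if data.promoter_interval.contains(v.chrom, v.pos0)
        and v.strain_calls.get(carrier) == v.alt_allele
    ]
    alt_seq, _ = tfbs.apply_variants(
        data.promoter.ref_seq, promoter_vars,
        origin_pos=data.promoter_interval.start + 1,
    )
    hits = []
    for pwm in data.pwms:
        hits += tfbs.scan_sequence(pwm, data.promoter.ref_seq, args.rel_threshold, "ref")
        hits += tfbs.scan_sequence(pwm, alt_seq, args.rel_threshold, "alt")
    tfbs.hits_to_frame(hits).to_csv(args.out_dir / "tfbs_hits.tsv", sep="\t", index=False)

    deltas = tfbs.delta_sites(data.pwms, data.promoter.ref_seq, alt_seq, args.rel_threshold)
    tfbs.deltas_to_frame(deltas).to_csv(args.out_dir / "tfbs_deltas.tsv", sep="\t", index=False)
    print(f"{len(promoter_vars)} carrier variant(s) in the 2-kb promoter; "
          f"{len(hits)} passing sites across both haplotypes")
    for d in deltas:
        print(f"  {d.pwm_name}: {d.status}")
    print("planted disruption recovered:",
          [d.pwm_name for d in deltas] == data.truth.disrupted_tfs)


if __name__ == "__main__":
    main()
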