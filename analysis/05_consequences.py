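"""Variant-consequence classification in the critical interval.

Classifies every strain variant of the refined interval against the gene
models (most-severe category per overlapping gene; coding SNPs translated
strand-aware) and writes the per-call table plus the variant-type summary
(SNPs / indels / distinct genes per category) under results/.
"""

import argparse
from pathlib import Path

from qtlfine import annotate, consequence
from qtlfine.pipeline import build_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--upstream-window", type=int, default=5000)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    data = build_study(seed=args.seed)
    critical_genes, _ = annotate.genes_in_interval(data.genes, data.critical_interval)
    calls = consequence.classify_table(
        data.variants, critical_genes, data.region_seq, args.upstream_window
    )
    consequence.calls_to_frame(calls).to_csv(
        args.out_dir / "consequence_calls.tsv", sep="\t", index=False
    )
    summary = consequence.consequence_summary(calls)
    summary.to_csv(args.out_dir / "consequence_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    protein = [c for c in calls if c.protein_change]
    for c in protein:
        print(f"protein-altering: {c.gene} {c.category} {c.protein_change} "
              f"({c.variant.rsid or 'novel'})")
    fs = [c for c in calls if c.category == consequence.FRAMESHIFT]
    for c in fs:
        print(f"frameshift: {c.gene} ({c.variant.rsid or 'novel'})")


if __name__ == "__main__":
    main()
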