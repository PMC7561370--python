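"""Evidence combination: narrow an interval's genes to candidates.

A gene is a candidate iff it lies in the critical interval AND in a
polymorphic haplotype block AND shows at least one line of functional
evidence — differential islet expression or a protein-altering variant
(missense / frameshift / stop gained).  TFBS alterations annotate the
report but do not by themselves qualify a gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import genes_in_blocks, genes_in_interval
from .consequence import FRAMESHIFT, MISSENSE, STOP_GAINED, ConsequenceCall
from .expression import DEResult
from .genes import GeneModel
from .intervals import GenomicInterval

QUALIFYING_CODING = (MISSENSE, FRAMESHIFT, STOP_GAINED)
_CODING_RANK = {STOP_GAINED: 0, FRAMESHIFT: 1, MISSENSE: 2}


@dataclass(frozen=True)
class CandidateReport:
    gene: str
    gene_name: str
    in_critical_interval: bool
    in_polymorphic_block: bool
    de_flag: bool
    coding_variant: str  # none | missense | frameshift | stop_gained
    tfbs_delta_count: int
    candidate: bool


def build_report(
    genes: list[GeneModel],
    interval: GenomicInterval,
    blocks,
    de_results: list[DEResult],
    consequence_calls: list[ConsequenceCall],
    tfbs_deltas_by_gene: dict[str, int] | None = None,
) -> list[CandidateReport]:
    """One row per gene in the critical interval, candidates first.

    Genes absent from the DE results count as not differentially expressed;
    the most severe qualifying coding category per gene is reported.
    """
    subset, _ = genes_in_interval(genes, interval)
    if len({g.gene_id for g in subset}) != len(subset):
        raise ValueError("duplicate gene_ids in input gene models")
    block_ids = {g.gene_id for g in genes_in_blocks(genes, blocks)}
    de_ids = {r.gene for r in de_results if r.de_flag}
    coding: dict[str, str] = {}
    for call in consequence_calls:
        if call.gene and call.category in QUALIFYING_CODING:
            prev = coding.get(call.gene)
            if prev is None or _CODING_RANK[call.category] < _CODING_RANK[prev]:
                coding[call.gene] = call.category
    tf_counts = tfbs_deltas_by_gene or {}

    rows = []
    for g in subset:
        in_block = g.gene_id in block_ids
        de = g.gene_id in de_ids or g.gene_name in de_ids
        cv = coding.get(g.gene_id, "none")
        rows.append(
            CandidateReport(
                gene=g.gene_id,
                gene_name=g.gene_name,
                in_critical_interval=True,
                in_polymorphic_block=in_block,
                de_flag=de,
                coding_variant=cv,
                tfbs_delta_count=int(tf_counts.get(g.gene_id, tf_counts.get(g.gene_name, 0))),
                candidate=in_block and (de or cv != "none"),
            )
        )
    order = {g.gene_id: g.interval.start for g in subset}
    rows.sort(key=lambda r: (not r.candidate, order[r.gene]))
    return rows


def report_to_frame(report: list[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "name": r.gene_name,
                "in_critical_interval": r.in_critical_interval,
                "in_polymorphic_block": r.in_polymorphic_block,
                "de_flag": r.de_flag,
                "coding_variant": r.coding_variant,
                "tfbs_delta_count": r.tfbs_delta_count,
                "candidate": r.candidate,
            }
            for r in report
        ],
        columns=[
            "gene", "name", "in_critical_interval", "in_polymorphic_block",
            "de_flag", "coding_variant", "tfbs_delta_count", "candidate",
        ],
    )


def evidence_matrix(report: list[CandidateReport]) -> pd.DataFrame:
    """Long-form (gene, evidence_type, value) rendering of the report."""
    evidence_types = [
        "in_critical_interval", "in_polymorphic_block", "de_flag",
        "coding_variant", "tfbs_delta_count", "candidate",
    ]
    rows = []
    for r in report:
        for ev in evidence_types:
            rows.append({"gene": r.gene, "evidence_type": ev, "value": str(getattr(r, ev))})
    return pd.DataFrame(rows, columns=["gene", "evidence_type", "value"])


def evidence_matrix_to_report(frame: pd.DataFrame, names: dict[str, str] | None = None) -> list[CandidateReport]:
    """Inverse of :func:`evidence_matrix` (lossless round trip)."""
    names = names or {}
    out = []
    for gene, grp in frame.groupby("gene", sort=False):
        vals = dict(zip(grp["evidence_type"], grp["value"]))
        out.append(
            CandidateReport(
                gene=gene,
                gene_name=names.get(gene, gene),
                in_critical_interval=vals["in_critical_interval"] == "True",
                in_polymorphic_block=vals["in_polymorphic_block"] == "True",
                de_flag=vals["de_flag"] == "True",
                coding_variant=vals["coding_variant"],
                tfbs_delta_count=int(vals["tfbs_delta_count"]),
                candidate=vals["candidate"] == "True",
            )
        )
    return out


def funnel_summary(
    n_initial: int,
    n_critical: int,
    n_in_blocks: int,
    report: list[CandidateReport],
) -> str:
    """One-page plain-text narrowing summary (interval -> blocks -> candidates)."""
    candidates = [r for r in report if r.candidate]
    lines = [
        "Candidate-gene narrowing funnel",
        "===============================",
        f"genes in initial interval:   {n_initial}",
        f"genes in critical interval:  {n_critical}",
        f"genes in polymorphic blocks: {n_in_blocks}",
        f"candidate genes:             {len(candidates)}",
        "",
    ]
    for r in candidates:
        ev = []
        if r.de_flag:
            ev.append("differential islet expression")
        if r.coding_variant != "none":
            ev.append(f"{r.coding_variant} variant")
        if r.tfbs_delta_count:
            ev.append(f"{r.tfbs_delta_count} altered TFBS (annotation)")
        lines.append(f"  {r.gene_name}: " + "; ".join(ev))
    return "\n".join(lines) + "\n"
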