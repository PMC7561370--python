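"""Differential expression between genotype groups from an FPKM-like matrix.

Per gene, a pooled-variance two-sample t-test compares homozygous carrier
(D/D) islet samples against homozygous background (N/N) controls, by
default on log2(FPKM + 1) values (variance stabilization; the raw scale is
available behind a flag).  Fold changes are reported on the raw scale as
(mean_DD + eps) / (mean_NN + eps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_NN = "NN"
GROUP_DD = "DD"


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples expression values with a group map."""

    values: pd.DataFrame  # index = genes, columns = samples
    groups: dict[str, str]  # sample -> NN | DD

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        for grp in (GROUP_NN, GROUP_DD):
            if not any(g == grp for g in self.groups.values()):
                raise ValueError(f"group {grp} is empty")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def to_tsv(self, matrix_path, groups_path) -> None:
        self.values.rename_axis("gene").to_csv(matrix_path, sep="\t")
        pd.DataFrame(
            {"sample": list(self.values.columns),
             "group": [self.groups[s] for s in self.values.columns]}
        ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, groups_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        grp = pd.read_csv(groups_path, sep="\t")
        return cls(values, dict(zip(grp["sample"], grp["group"])))


@dataclass(frozen=True)
class DEResult:
    gene: str
    mean_nn: float
    mean_dd: float
    fold_change: float
    p_value: float  # NaN when undefined
    de_flag: bool
    q_value: float | None = None


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    log_scale: bool = True,
    eps: float = 0.01,
    adjust: bool = False,
) -> list[DEResult]:
    """Per-gene two-sided pooled-variance t-test between D/D and N/N.

    Genes with all-zero values in both groups, or zero pooled variance, get
    p = NaN and are never flagged.  With fewer than two samples in a group
    every p is NaN (a warning is emitted).  ``adjust=True`` additionally
    reports Benjamini-Hochberg q-values (the flag still uses raw p).
    """
    nn = matrix.samples_of(GROUP_NN)
    dd = matrix.samples_of(GROUP_DD)
    raw = matrix.values
    X = np.log2(raw + 1.0) if log_scale else raw
    degenerate = len(nn) < 2 or len(dd) < 2
    if degenerate:
        warnings.warn("fewer than 2 samples in a group; p-values undefined", stacklevel=2)
    results: list[DEResult] = []
    pvals: list[float] = []
    for gene in raw.index:
        a = X.loc[gene, nn].to_numpy(dtype=float)
        b = X.loc[gene, dd].to_numpy(dtype=float)
        mean_nn = float(raw.loc[gene, nn].mean())
        mean_dd = float(raw.loc[gene, dd].mean())
        fc = (mean_dd + eps) / (mean_nn + eps)
        if degenerate or (mean_nn == 0 and mean_dd == 0) or np.ptp(np.r_[a, b]) == 0:
            p = float("nan")
        else:
            p = float(stats.ttest_ind(b, a, equal_var=True).pvalue)
        pvals.append(p)
        results.append(DEResult(gene, mean_nn, mean_dd, fc, p, bool(p == p and p < alpha)))
    if adjust:
        parr = np.asarray(pvals)
        ok = np.isfinite(parr)
        q = np.full(len(parr), np.nan)
        if ok.any():
            q[ok] = multipletests(parr[ok], method="fdr_bh")[1]
        results = [
            DEResult(r.gene, r.mean_nn, r.mean_dd, r.fold_change, r.p_value, r.de_flag, float(qv))
            for r, qv in zip(results, q)
        ]
    return results


def de_in_interval(de_results: list[DEResult], genes, interval) -> list[DEResult]:
    """DE-flagged results whose gene lies in the interval (any overlap)."""
    from .annotate import genes_in_interval

    subset, _ = genes_in_interval(list(genes), interval)
    wanted = {g.gene_id for g in subset} | {g.gene_name for g in subset}
    return [r for r in de_results if r.de_flag and r.gene in wanted]


def de_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "mean_NN": r.mean_nn,
                "mean_DD": r.mean_dd,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "de_flag": r.de_flag,
                **({"q_value": r.q_value} if r.q_value is not None else {}),
            }
            for r in results
        ]
    )
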