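"""Single-marker LOD scan with permutation thresholds for an N2 backcross.

At a fully genotyped marker of a backcross (two genotype classes, N/N vs
N/D), maximum-likelihood interval mapping reduces to single-marker
regression, giving

    LOD = (n/2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares about the grand phenotype mean
and RSS1 about the genotype-class means.  Genome-wide significance comes
from the empirical distribution of the maximum LOD over phenotype
permutations (1,000 by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NN = "NN"
ND = "ND"
GENO_MISSING = "NA"

#: numeric coding used internally; missing -> -1
_CODE = {NN: 0, ND: 1, GENO_MISSING: -1}


@dataclass
class BackcrossCohort:
    """Genotypes and phenotypes of an N2 backcross population."""

    individuals: list[str]
    markers: list[tuple[str, str, int]]  # (marker_id, chrom, position_bp)
    genotypes: np.ndarray  # individuals x markers, int8 codes {0=NN, 1=ND, -1=missing}
    phenotypes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.individuals) or m != len(self.markers):
            raise ValueError("genotype matrix dimensions do not match labels")
        for name, vec in self.phenotypes.items():
            if len(vec) != n:
                raise ValueError(f"phenotype {name!r} length {len(vec)} != n={n}")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def marker_ids(self) -> list[str]:
        return [m[0] for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def phenotype(self, name: str) -> np.ndarray:
        if name not in self.phenotypes:
            raise KeyError(f"unknown phenotype {name!r}")
        return self.phenotypes[name]

    @classmethod
    def from_tsv(cls, geno_path, pheno_path) -> "BackcrossCohort":
        """Load from genotype TSV (rows=individuals, cells NN/ND/NA, marker
        columns named ``id@chrom:pos``) and phenotype TSV (one column per trait)."""
        geno = pd.read_csv(geno_path, sep="\t", index_col=0, dtype=str)
        pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
        markers = []
        for col in geno.columns:
            mid, loc = col.split("@")
            chrom, pos = loc.split(":")
            markers.append((mid, chrom, int(pos)))
        codes = geno.fillna(GENO_MISSING).apply(lambda c: c.map(_CODE)).to_numpy(dtype=np.int8)
        return cls(
            individuals=list(geno.index),
            markers=markers,
            genotypes=codes,
            phenotypes={c: pheno[c].to_numpy(dtype=float) for c in pheno.columns},
        )

    def to_tsv(self, geno_path, pheno_path) -> None:
        inv = {0: NN, 1: ND, -1: GENO_MISSING}
        cols = [f"{mid}@{chrom}:{pos}" for mid, chrom, pos in self.markers]
        geno = pd.DataFrame(
            [[inv[int(v)] for v in row] for row in self.genotypes],
            index=pd.Index(self.individuals, name="individual"),
            columns=cols,
        )
        geno.to_csv(geno_path, sep="\t")
        pd.DataFrame(self.phenotypes, index=pd.Index(self.individuals, name="individual")).to_csv(
            pheno_path, sep="\t"
        )


@dataclass
class LinkageResult:
    phenotype_name: str
    marker_ids: list[str]
    lod: np.ndarray  # per marker; NaN where unscorable
    zero_variance: bool = False
    permutation_threshold: float | None = None
    alpha: float | None = None
    peaks: list[str] = field(default_factory=list)
    effect_sizes: dict[str, dict] = field(default_factory=dict)

    def to_frame(self, cohort: BackcrossCohort) -> pd.DataFrame:
        thr = self.permutation_threshold
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chrom": [m[1] for m in cohort.markers],
                "pos": [m[2] for m in cohort.markers],
                "lod": self.lod,
                "significant": [
                    bool(thr is not None and np.isfinite(l) and l >= thr) for l in self.lod
                ],
            }
        )


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n) -> np.ndarray:
    """LOD with the zero-variance convention: RSS0 == 0 -> LOD 0."""
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    out = np.zeros(np.broadcast(rss0, rss1).shape, dtype=float)
    ok = rss0 > 0
    ratio = np.divide(rss0, np.maximum(rss1, 1e-300), where=ok, out=np.ones_like(out))
    np.log10(ratio, where=ok, out=out)
    out *= np.asarray(n, dtype=float) / 2.0
    return np.maximum(out, 0.0)


def _marker_lod_matrix(g: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD for every (marker, phenotype column) pair; no missing genotypes.

    g: individuals x markers in {0,1}; Y: individuals x P.  Markers with an
    empty genotype class give NaN.
    """
    n = g.shape[0]
    n1 = g.sum(axis=0).astype(float)  # per marker
    n0 = n - n1
    tot = Y.sum(axis=0)  # per phenotype
    sq = (Y**2).sum(axis=0)
    s1 = g.T @ Y  # markers x P
    s0 = tot[None, :] - s1
    rss0 = sq - tot**2 / n  # per phenotype
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = sq[None, :] - s1**2 / n1[:, None] - s0**2 / n0[:, None]
    rss1 = np.maximum(rss1, 0.0)
    lod = _lod_from_rss(np.broadcast_to(rss0[None, :], rss1.shape), rss1, n)
    lod[(n1 < 2) | (n0 < 2), :] = np.nan
    return lod


def lod_scan(cohort: BackcrossCohort, phenotype_name: str) -> LinkageResult:
    """Per-marker LOD for one phenotype.

    Individuals with a missing genotype are dropped at that marker only;
    a marker needs >= 2 individuals in each genotype class to be scored
    (otherwise LOD is NaN).  A zero-variance phenotype gives LOD 0
    everywhere, flagged on the result.
    """
    y = np.asarray(cohort.phenotype(phenotype_name), dtype=float)
    g = cohort.genotypes
    lods = np.full(g.shape[1], np.nan)
    zero_var = bool(np.ptp(y) == 0) if len(y) else True
    for j in range(g.shape[1]):
        mask = g[:, j] >= 0
        gj, yj = g[mask, j], y[mask]
        n1 = int(gj.sum())
        n0 = len(gj) - n1
        if n0 < 2 or n1 < 2:
            continue
        lods[j] = _marker_lod_matrix(gj[:, None].astype(float), yj[:, None])[0, 0]
    return LinkageResult(phenotype_name, cohort.marker_ids, lods, zero_variance=zero_var)


def _max_lod_over_permutations(cohort: BackcrossCohort, Y: np.ndarray) -> np.ndarray:
    """Genome-wide max LOD for each phenotype column of Y (permutations)."""
    g = cohort.genotypes
    if (g >= 0).all():
        lod = _marker_lod_matrix(g.astype(float), Y)
        return np.nanmax(lod, axis=0)
    maxima = np.full(Y.shape[1], 0.0)
    any_scored = np.zeros(Y.shape[1], dtype=bool)
    for j in range(g.shape[1]):
        mask = g[:, j] >= 0
        gj = g[mask, j].astype(float)[:, None]
        n1 = int(gj.sum())
        if n1 < 2 or (len(gj) - n1) < 2:
            continue
        lod_j = _marker_lod_matrix(gj, Y[mask, :])[0]
        maxima = np.fmax(maxima, lod_j)
        any_scored |= np.isfinite(lod_j)
    maxima[~any_scored] = np.nan
    return maxima


def permutation_threshold(
    cohort: BackcrossCohort,
    phenotype_name: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    exhaustive: bool = False,
) -> float:
    """Genome-wide (1 - alpha) quantile of the permutation max-LOD null.

    Phenotypes are shuffled across individuals; the empirical quantile uses
    the conservative "higher" interpolation.  With ``exhaustive=True`` all
    n! orderings are enumerated (small cohorts only).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not exhaustive and n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    y = np.asarray(cohort.phenotype(phenotype_name), dtype=float)
    n = len(y)
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    maxima_all = []
    # chunk to bound the permutation matrix at ~10^7 entries
    chunk = max(1, int(1e7) // max(n, 1))
    for i in range(0, len(perms), chunk):
        Y = y[perms[i : i + chunk]].T  # n x chunk
        maxima_all.append(_max_lod_over_permutations(cohort, Y))
    maxima = np.concatenate(maxima_all)
    maxima = maxima[np.isfinite(maxima)]
    if len(maxima) == 0:
        return 0.0
    return float(np.quantile(maxima, 1 - alpha, method="higher"))


def effect_summary(cohort: BackcrossCohort, phenotype_name: str, marker_id: str, welch: bool = False) -> dict:
    """Group means +/- SEM and a two-sided two-sample t-test at one marker.

    Pooled-variance Student's t by default; Welch behind the flag.  A group
    with fewer than two observations gives p = NaN.
    """
    j = cohort.marker_index(marker_id)
    y = np.asarray(cohort.phenotype(phenotype_name), dtype=float)
    g = cohort.genotypes[:, j]
    out = {"marker": marker_id, "phenotype": phenotype_name}
    for label, code in ((NN, 0), (ND, 1)):
        vals = y[g == code]
        out[label] = {
            "n": int(len(vals)),
            "mean": float(np.mean(vals)) if len(vals) else math.nan,
            "sem": float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan,
        }
    a, b = y[g == 0], y[g == 1]
    if len(a) < 2 or len(b) < 2:
        out["t"], out["p"] = math.nan, math.nan
        return out
    if np.ptp(np.concatenate([a, b])) == 0:
        out["t"], out["p"] = 0.0, 1.0
        return out
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    out["t"], out["p"] = float(t), float(p)
    return out


def scan_with_threshold(
    cohort: BackcrossCohort,
    phenotype_name: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> LinkageResult:
    """LOD scan + permutation threshold + effect summaries at the peaks.

    Peaks are markers at or above the threshold; ties in the maximum are
    broken toward the lowest genomic coordinate.
    """
    result = lod_scan(cohort, phenotype_name)
    thr = permutation_threshold(cohort, phenotype_name, n_perm=n_perm, alpha=alpha, seed=seed)
    result.permutation_threshold = thr
    result.alpha = alpha
    finite = np.nan_to_num(result.lod, nan=-1.0)
    result.peaks = [
        mid for mid, l in zip(result.marker_ids, finite) if l >= thr and thr > 0
    ]
    for mid in result.peaks:
        result.effect_sizes[mid] = effect_summary(cohort, phenotype_name, mid)
    return result


def peak_marker(result: LinkageResult, cohort: BackcrossCohort) -> str:
    """Marker with the maximum LOD; ties broken by lowest coordinate."""
    order = sorted(
        range(len(result.marker_ids)),
        key=lambda j: (cohort.markers[j][1], cohort.markers[j][2]),
    )
    best, best_lod = None, -np.inf
    for j in order:
        l = result.lod[j]
        if np.isfinite(l) and l > best_lod:
            best, best_lod = result.marker_ids[j], l
    if best is None:
        raise ValueError("no scorable marker")
    return best


def diabetes_prevalence(bg_values, cutoff: float = 16.6) -> float:
    """Percent of animals with blood glucose strictly above the cutoff (mM)."""
    vals = np.asarray(list(bg_values), dtype=float)
    if len(vals) == 0:
        raise ValueError("empty blood-glucose vector")
    return float(100.0 * np.count_nonzero(vals > cutoff) / len(vals))
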