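"""PWM construction from JASPAR count matrices and allele-aware scanning.

A position frequency matrix (PFM) of observed base counts becomes a
log-odds position weight matrix (PWM, in bits):

    w[b, i] = log2( (n[b, i] + p * q_b) / (N_i + p) / q_b )

with pseudocount p split by the background frequencies q.  A window's
relative score is (score - min_score) / (max_score - min_score), so 1.0 is
the consensus; sites are called at a relative-score threshold (0.80 by
default).  Scanning both haplotypes of a promoter and comparing passing
sites yields variant-altered (lost / gained) binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

UNIFORM_BG = {b: 0.25 for b in BASES}


@dataclass
class PWM:
    """Log-odds position weight matrix over A,C,G,T (rows) in bits."""

    name: str
    matrix: np.ndarray  # 4 x L
    background: dict[str, float]
    pseudocount: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def relative(self, score: float) -> float:
        span = self.max_score - self.min_score
        return (score - self.min_score) / span if span > 0 else 1.0


@dataclass(frozen=True)
class TFBSHit:
    pwm_name: str
    allele: str  # "ref" | "alt"
    position: int  # 1-based on the scanned sequence
    strand: str
    score: float
    relative_score: float


@dataclass(frozen=True)
class TFBSDelta:
    pwm_name: str
    status: str  # "lost_in_alt" | "gained_in_alt"
    best_ref: TFBSHit | None
    best_alt: TFBSHit | None


def pfm_to_pwm(
    pfm_counts: dict[str, list[float]] | np.ndarray,
    name: str = "pwm",
    background: dict[str, float] | None = None,
    pseudocount: float = 0.8,
) -> PWM:
    """Convert base counts to a log-odds PWM in bits."""
    bg = UNIFORM_BG if background is None else background
    if isinstance(pfm_counts, dict):
        counts = np.array([pfm_counts[b] for b in BASES], dtype=float)
    else:
        counts = np.asarray(pfm_counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("PFM must have 4 base rows (A,C,G,T)")
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("zero column total with zero pseudocount")
    q = np.array([bg[b] for b in BASES], dtype=float)[:, None]
    prob = (counts + pseudocount * q) / (totals + pseudocount)[None, :]
    with np.errstate(divide="ignore"):  # zero prob with pc=0 -> -inf log-odds
        matrix = np.log2(prob / q)
    return PWM(name, matrix, dict(bg), pseudocount)


def read_jaspar_pfms(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Parse JASPAR-style PFM text: '>ID name' then 4 labeled count rows.

    Accepts both the bracketed ``A [ 1 2 3 ]`` and plain ``A 1 2 3`` row
    styles.
    """
    entries: list[tuple[str, np.ndarray]] = []
    name = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, name
        if name is not None:
            if set(rows) != set(BASES):
                raise ValueError(f"PFM {name!r} missing base rows")
            entries.append((name, np.array([rows[b] for b in BASES], dtype=float)))
        rows, name = {}, None

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[-1] if len(line[1:].split()) > 1 else line[1:].strip()
        else:
            base = line[0].upper()
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    flush()
    return entries


def write_jaspar_pfms(entries: list[tuple[str, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (name, counts) in enumerate(entries, 1):
            fh.write(f">MA{i:04d}.1 {name}\n")
            for b, row in zip(BASES, counts):
                fh.write(f"{b} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


def _encode(sequence: str) -> np.ndarray:
    """Sequence -> base indices; anything not ACGT becomes -1."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Score of every window start on the encoded (+) sequence; NaN where N."""
    L = pwm.length
    n_win = len(encoded) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for offset in range(L):
        col = encoded[offset : offset + n_win]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, pwm.matrix[np.clip(col, 0, 3), offset], 0.0)
    scores[~valid] = np.nan
    return scores


def scan_sequence(pwm: PWM, sequence: str, rel_threshold: float = 0.80, allele: str = "ref") -> list[TFBSHit]:
    """All positions x strands whose relative score passes the threshold.

    Positions are 1-based window starts on the given sequence; the minus
    strand scores the reverse complement, reported at the window's position
    on the forward sequence.  Windows containing N are skipped.
    """
    hits: list[TFBSHit] = []
    n = len(sequence)
    fwd = _window_scores(pwm, _encode(sequence))
    rev = _window_scores(pwm, _encode(revcomp(sequence)))
    for strand, scores in (("+", fwd), ("-", rev)):
        for w, s in enumerate(scores):
            if np.isnan(s):
                continue
            rel = pwm.relative(float(s))
            if rel >= rel_threshold:
                pos = w + 1 if strand == "+" else n - pwm.length - w + 1
                hits.append(TFBSHit(pwm.name, allele, pos, strand, float(s), rel))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def apply_variants(ref_sequence: str, variants, origin_pos: int) -> tuple[str, list[int | None]]:
    """Apply SNPs/indels to a sequence; return the alt haplotype + coordinate map.

    ``variants`` carry genomic 1-based positions; ``origin_pos`` is the
    genomic 1-based position of the sequence's first base.  Variants are
    applied right-to-left so earlier coordinates stay valid.  The returned
    map gives, per alt-sequence position (0-based), the originating ref
    position, or None for inserted bases.

    Overlapping variants, variants outside the sequence, and reference
    alleles that disagree with the sequence are fatal.
    """
    vs = sorted(variants, key=lambda v: v.pos)
    spans = []
    for v in vs:
        off = v.pos - origin_pos
        if off < 0 or off + len(v.ref_allele) > len(ref_sequence):
            raise ValueError(f"variant at {v.pos} outside sequence [{origin_pos}, ...]")
        if ref_sequence[off : off + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(
                f"reference allele mismatch at {v.pos}: sequence has "
                f"{ref_sequence[off:off + len(v.ref_allele)]!r}, variant {v.ref_allele!r}"
            )
        spans.append((off, off + len(v.ref_allele), v.alt_allele))
    for (s1, e1, _), (s2, _e2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping variants")
    alt = list(ref_sequence)
    coord: list[list[int | None]] = [[i] for i in range(len(ref_sequence))]
    for start, end, alt_allele in reversed(spans):
        alt[start:end] = list(alt_allele)
        coord[start:end] = [[start]] + [[None]] * (len(alt_allele) - 1) if alt_allele else []
    flat = [c[0] for c in coord]
    return "".join(alt), flat


def delta_sites(
    pwms: list[PWM],
    ref_sequence: str,
    alt_sequence: str,
    rel_threshold: float = 0.80,
) -> list[TFBSDelta]:
    """Per PWM, sites passing the threshold on exactly one haplotype.

    A PWM passing on the reference but not the alternate haplotype is
    ``lost_in_alt`` (and vice versa); PWMs passing or failing on both are
    not reported.
    """
    deltas: list[TFBSDelta] = []
    for pwm in pwms:
        ref_hits = scan_sequence(pwm, ref_sequence, rel_threshold, allele="ref")
        alt_hits = scan_sequence(pwm, alt_sequence, rel_threshold, allele="alt")
        best_ref = max(ref_hits, key=lambda h: h.relative_score, default=None)
        best_alt = max(alt_hits, key=lambda h: h.relative_score, default=None)
        if ref_hits and not alt_hits:
            deltas.append(TFBSDelta(pwm.name, "lost_in_alt", best_ref, None))
        elif alt_hits and not ref_hits:
            deltas.append(TFBSDelta(pwm.name, "gained_in_alt", None, best_alt))
    return deltas


def hits_to_frame(hits: list[TFBSHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pwm": h.pwm_name, "allele": h.allele, "position": h.position,
             "strand": h.strand, "score": h.score, "relative_score": h.relative_score}
            for h in hits
        ],
        columns=["pwm", "allele", "position", "strand", "score", "relative_score"],
    )


def deltas_to_frame(deltas: list[TFBSDelta]) -> pd.DataFrame:
    rows = []
    for d in deltas:
        rows.append(
            {
                "pwm": d.pwm_name,
                "status": d.status,
                "ref_best_rel": d.best_ref.relative_score if d.best_ref else float("nan"),
                "alt_best_rel": d.best_alt.relative_score if d.best_alt else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["pwm", "status", "ref_best_rel", "alt_best_rel"])
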