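"""Position-weight-matrix scanning with exact score-distribution p-values.

JASPAR position frequency matrices are turned into log2-odds PWMs against a
background model, the exact null distribution of scores for random background
sequences is computed by dynamic-programming convolution of the per-column
score distributions on a discretized grid, and peak sequences are scanned on
both strands, emitting hits below a p-value threshold (default 1e-4).

Scores are quantized to a fixed granularity (default 1e-3 bits) and both the
null distribution and the scanner operate on the same quantized integers, so
the p-value attached to a hit is exactly the null tail mass at its score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeModel, GenomicInterval, IntervalSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: score-grid granularity in bits
GRANULARITY = 1e-3


@dataclass
class PFM:
    """Position frequency matrix: 4 x L counts, rows A, C, G, T."""

    tf_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.ndim != 2:
            raise ValueError("PFM must be 4 x L")
        if np.any(self.matrix < 0):
            raise ValueError("PFM counts must be >= 0")
        if np.any(self.matrix.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have positive total count")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=0))


@dataclass
class PWM:
    """Log2-odds matrix with its background and the quantized integer form."""

    tf_name: str
    matrix: np.ndarray  # 4 x L, bits
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def int_matrix(self) -> np.ndarray:
        """Scores rounded to the grid, as integers (units of GRANULARITY)."""
        return np.rint(self.matrix / GRANULARITY).astype(np.int64)

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.tf_name,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )


@dataclass
class MotifHit:
    tf_name: str
    interval: GenomicInterval
    strand: str
    score: float  # log2-odds, bits
    p_value: float


def parse_jaspar(path) -> list[PFM]:
    """Parse a JASPAR-format PFM file (possibly multi-record)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise ValueError(f"malformed JASPAR file {path}: {exc}") from exc
        out = []
        for m in records:
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            name = m.name or m.matrix_id or "motif"
            out.append(PFM(str(name), counts))
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def write_jaspar(pfms: list[PFM], path) -> None:
    with open(path, "w") as fh:
        for i, pfm in enumerate(pfms):
            fh.write(f">M{i:04d} {pfm.tf_name}\n")
            for b, row in zip(BASES, pfm.matrix):
                cells = " ".join(f"{int(c):6d}" for c in row)
                fh.write(f"{b}  [ {cells} ]\n")


def build_pwm(
    pfm: PFM,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> PWM:
    """Log2-odds PWM: entry = log2(((count + pc*bg) / (colsum + pc)) / bg)."""
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background probabilities must be > 0")
    background = background / background.sum()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    colsum = pfm.matrix.sum(axis=0)
    prob = (pfm.matrix + pseudocount * background[:, None]) / (colsum + pseudocount)
    with np.errstate(divide="ignore"):
        lo = np.log2(prob / background[:, None])
    return PWM(pfm.tf_name, lo, background, pseudocount)


@dataclass
class ScoreDistribution:
    """Exact null distribution of quantized PWM scores under the background.

    ``support`` holds the integer grid scores (units of GRANULARITY) with
    nonzero probability mass ``pmf``; ``survival[k]`` = P(S >= support[k]).
    """

    support: np.ndarray
    pmf: np.ndarray
    survival: np.ndarray

    def pvalue(self, score_bits: float) -> float:
        """P(S >= score) for a score in bits (snapped onto the grid)."""
        q = int(np.rint(score_bits / GRANULARITY))
        return self.pvalue_int(q)

    def pvalue_int(self, q: int) -> float:
        k = int(np.searchsorted(self.support, q, side="left"))
        if k >= len(self.support):
            return 0.0
        return float(self.survival[k])

    def threshold_int(self, p_threshold: float) -> int:
        """Smallest grid score whose p-value is strictly below the threshold.

        Returns a score larger than any attainable one when no score passes.
        """
        passing = self.survival < p_threshold
        if not np.any(passing):
            return int(self.support[-1]) + 1
        return int(self.support[np.argmax(passing)])


def score_pvalues(pwm: PWM) -> ScoreDistribution:
    """Null distribution of scores by DP convolution over motif columns.

    For each column the quantized score of each base occurs with its
    background probability; the total-score distribution is the convolution
    across columns.  Exact on the quantized grid.
    """
    im = pwm.int_matrix
    bg = pwm.background
    lo_total = int(im.min(axis=0).sum())
    hi_total = int(im.max(axis=0).sum())
    width = hi_total - lo_total + 1
    dist = np.zeros(width)
    dist[0] = 1.0  # offset: index 0 == score lo_total
    col_lo = im.min(axis=0)
    filled = 1
    for j in range(pwm.length):
        new = np.zeros(width)
        span = int(im[:, j].max() - col_lo[j]) + 1
        for b in range(4):
            shift = int(im[b, j] - col_lo[j])
            new[shift : shift + filled] += bg[b] * dist[:filled]
        filled += span - 1
        dist = new
    nz = np.nonzero(dist)[0]
    support = nz + lo_total
    pmf = dist[nz]
    survival = np.cumsum(pmf[::-1])[::-1]
    np.minimum(survival, 1.0, out=survival)
    return ScoreDistribution(support.astype(np.int64), pmf, survival)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(encoded: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Quantized score of every length-L window; windows with N get -2^62."""
    L = int_matrix.shape[1]
    n_win = len(encoded) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        col = encoded[j : j + n_win]
        bad = col < 0
        valid &= ~bad
        safe = np.where(bad, 0, col)
        scores += int_matrix[safe, j]
    scores[~valid] = np.int64(-(2**62))
    return scores


def scan(
    pwm: PWM,
    peaks: IntervalSet,
    genome: GenomeModel,
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan peak sequences on both strands; emit hits with p < p_threshold.

    Minus-strand hits (matches to the reverse complement) are reported on the
    forward-coordinate interval they cover.  Windows containing N are skipped.
    """
    seqs = genome.require_sequence()
    dist = score_pvalues(pwm)
    thr = dist.threshold_int(p_threshold)
    rc = pwm.reverse_complement()
    mats = {"+": pwm.int_matrix, "-": rc.int_matrix}
    hits: list[MotifHit] = []
    L = pwm.length
    for peak in peaks:
        genome.check(peak)
        encoded = encode_sequence(seqs[peak.chrom][peak.start : peak.end])
        for strand, mat in mats.items():
            ws = _window_scores(encoded, mat)
            for off in np.nonzero(ws >= thr)[0]:
                q = int(ws[off])
                hits.append(
                    MotifHit(
                        pwm.tf_name,
                        GenomicInterval(
                            peak.chrom, peak.start + int(off), peak.start + int(off) + L
                        ),
                        strand,
                        q * GRANULARITY,
                        dist.pvalue_int(q),
                    )
                )
    return hits


def hits_to_intervals(hits: list[MotifHit], name: str = "hits") -> IntervalSet:
    return IntervalSet(name, [h.interval for h in hits])


def write_hits(hits: list[MotifHit], path) -> None:
    """BED6+1: chrom, start, end, TF name, log2-odds score, strand, p-value."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
                f"{h.tf_name}\t{h.score:.4f}\t{h.strand}\t{h.p_value:.6g}\n"
            )


def read_hits(path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                MotifHit(
                    f[3],
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    f[5],
                    float(f[4]),
                    float(f[6]) if len(f) > 6 else float("nan"),
                )
            )
    return hits
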