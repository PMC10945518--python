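"""Dyad-anchored TF binding-motif profiles and nucleosome-position statistics.

Every motif hit is assigned to the nucleosome dyad closest to its midpoint
and each of its bases increments the profile at its offset from that dyad
(window +/- 1000 bp).  From the profile we derive the occupancy correlation
(+/- 400 bp Pearson), and the end/dyad binding ratio R_end/dyad: motif bases
at the nucleosomal DNA ends (superhelical locations +/-5.5 to +/-7) divided
by motif bases near the dyad (SHL 0 to +/-1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dyads import DyadMap
from .motifs import MotifHit

#: bp per superhelical location: 73 bp from dyad to DNA end over 7 turns
BP_PER_SHL = 73.0 / 7.0
END_SHL = (5.5, 7.0)
DYAD_SHL = (0.0, 1.5)


@dataclass
class MotifProfile:
    """Per-offset motif base counts X(i), i in [-flank, +flank]."""

    tf_name: str
    cell_line: str
    counts: np.ndarray
    flank: int = 1000
    n_motif_bp: int = 0
    nr_motif_bp: int = field(default=0)  # motif bases overlapping NRs (QC)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != 2 * self.flank + 1:
            raise ValueError("profile length must be 2*flank+1")

    def at(self, offset: int) -> int:
        return int(self.counts[offset + self.flank])

    def window_sum(self, offsets: np.ndarray) -> int:
        return int(self.counts[offsets + self.flank].sum())


def build_profile(
    hits: list[MotifHit],
    dyads: DyadMap,
    flank: int = 1000,
    tf_name: str = "",
    cell_line: str = "",
) -> MotifProfile:
    """Assign each hit to its closest dyad (by hit midpoint; tie -> lower
    coordinate dyad) and count every hit base at its dyad-relative offset.

    Both strands are counted in genomic orientation; no flipping.
    """
    if dyads.n_dyads() == 0:
        raise ValueError("empty dyad map")
    counts = np.zeros(2 * flank + 1, dtype=np.int64)
    nr_bp = 0
    for h in hits:
        pos = dyads.positions(h.interval.chrom)
        if len(pos) == 0:
            continue
        mid = h.interval.start + len(h.interval) // 2
        k = int(np.searchsorted(pos, mid))
        best = None
        for cand in (k - 1, k):
            if 0 <= cand < len(pos):
                d = abs(int(pos[cand]) - mid)
                # strict < keeps the lower-coordinate dyad on exact ties
                if best is None or d < best[0]:
                    best = (d, int(pos[cand]))
        dyad = best[1]
        offs = np.arange(h.interval.start, h.interval.end) - dyad
        inside = offs[(offs >= -flank) & (offs <= flank)]
        counts[inside + flank] += 1
        nr_bp += int(np.sum(np.abs(offs) <= 73))
    prof = MotifProfile(
        tf_name or (hits[0].tf_name if hits else ""),
        cell_line,
        counts,
        flank,
        int(counts.sum()),
    )
    prof.nr_motif_bp = nr_bp
    return prof


def normalize_profile(p: MotifProfile | np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant profile maps to all zeros."""
    x = p.counts if isinstance(p, MotifProfile) else np.asarray(p)
    x = x.astype(float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def occupancy_correlation(
    p: MotifProfile, occupancy: np.ndarray, flank: int = 400
) -> tuple[float, float]:
    """Pearson correlation of the motif profile with nucleosome occupancy
    over offsets -flank..+flank; two-sided p from the t distribution."""
    prof = p.counts[p.flank - flank : p.flank + flank + 1].astype(float)
    occ = np.asarray(occupancy, dtype=float)
    occ_flank = (len(occ) - 1) // 2
    occ = occ[occ_flank - flank : occ_flank + flank + 1]
    if prof.std() == 0 or occ.std() == 0:
        raise ValueError("constant input")
    r, pval = stats.pearsonr(prof, occ)
    return float(r), float(pval)


def shl_to_offsets(shl_lo: float, shl_hi: float) -> np.ndarray:
    """bp offsets i with round(shl_lo*73/7) <= |i| <= round(shl_hi*73/7),
    on both nucleosome halves.  Rounding is half-away-from-zero."""
    if not (0 <= shl_lo < shl_hi or (shl_lo == shl_hi == 0)):
        raise ValueError("require 0 <= shl_lo < shl_hi")
    if shl_hi > 7:
        raise ValueError("SHL beyond the DNA end (7)")

    def rnd(x: float) -> int:
        return int(math.floor(x + 0.5))

    lo_bp, hi_bp = rnd(shl_lo * BP_PER_SHL), rnd(shl_hi * BP_PER_SHL)
    offs = np.arange(-hi_bp, hi_bp + 1)
    return offs[np.abs(offs) >= lo_bp]


def end_dyad_ratio(
    p: MotifProfile,
    end_shl: tuple[float, float] = END_SHL,
    dyad_shl: tuple[float, float] = DYAD_SHL,
    allow_infinite: bool = False,
) -> float:
    """R_end/dyad: motif bases in the end windows over those near the dyad."""
    end_total = p.window_sum(shl_to_offsets(*end_shl))
    dyad_total = p.window_sum(shl_to_offsets(*dyad_shl))
    if dyad_total == 0:
        if allow_infinite:
            return float("inf")
        raise ValueError("no motif bases in the dyad window")
    return end_total / dyad_total


def symmetry_pcc(p: MotifProfile, half: int = 73) -> float:
    """Pearson correlation between the two nucleosomal halves
    (offsets +1..+half vs. -1..-half mirrored)."""
    plus = p.counts[p.flank + 1 : p.flank + half + 1].astype(float)
    minus = p.counts[p.flank - half : p.flank][::-1].astype(float)
    if plus.std() == 0 or minus.std() == 0:
        return float("nan")
    return float(stats.pearsonr(plus, minus)[0])


def write_profile(p: MotifProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tcount\n")
        for off in range(-p.flank, p.flank + 1):
            fh.write(f"{off}\t{p.at(off)}\n")
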