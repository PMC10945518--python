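"""Open chromatin, NDRs, active enhancers, and conserved/differential regions.

Open chromatin is the DNase narrow-peak center flanked by 1000 bp on each
side.  Nucleosome-depleted regions (NDRs) are the open-chromatin bases not
covered by any mono-nucleosome fragment (120-180 bp) from any replicate.
Active enhancers are open regions overlapping both H3K27ac and H3K4me1
peaks.  Conserved open regions share more than 80% of their bases with the
open set of at least one other cell line; differentially open regions overlap
another line's open set by less than 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dyads import OCC_LEN_MAX, OCC_LEN_MIN
from .intervals import (
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    coverage_fractions,
    overlap_stats,
    subtract_coverage,
)


@dataclass
class CellLineAnnotation:
    cell_line: str
    open_regions: IntervalSet
    ndr_regions: IntervalSet
    enhancer_regions: IntervalSet = field(default_factory=IntervalSet)
    provenance: dict = field(default_factory=dict)


def open_chromatin(
    dnase_peaks: IntervalSet, genome: GenomeModel, flank: int = 1000
) -> IntervalSet:
    """Open-chromatin regions: peak center +/- flank, clipped and merged.

    The center is the narrowPeak summit when recorded, the interval midpoint
    otherwise.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for peak in dnase_peaks:
        c = peak.center
        n = genome.chrom_sizes[peak.chrom]
        s, e = max(c - flank, 0), min(c + flank + 1, n)
        if s < e:
            out.append(GenomicInterval(peak.chrom, s, e))
    return IntervalSet("open", out).canonicalize() if out else IntervalSet("open")


def ndr_regions(
    open_regions: IntervalSet,
    fragment_sets: list[IntervalSet],
    len_min: int = OCC_LEN_MIN,
    len_max: int = OCC_LEN_MAX,
    mode: str = "subtract",
) -> IntervalSet:
    """Nucleosome-depleted regions within open chromatin.

    mode='subtract' (default): per-base subtraction of all size-filtered
    fragments, returning the uncovered sub-intervals of each open region.
    mode='strict': keep only whole open regions with zero fragment overlap.
    """
    filtered = [
        iv
        for fs in fragment_sets
        for iv in fs
        if len_min <= len(iv) <= len_max
    ]
    covers = IntervalSet("fragments", filtered)
    if mode == "subtract":
        out = subtract_coverage(open_regions, covers)
    elif mode == "strict":
        kept = [
            iv for iv in open_regions if overlap_stats(iv, covers)[0] == 0
        ]
        out = IntervalSet(open_regions.name, kept)
    else:
        raise ValueError(f"unknown NDR mode {mode!r}")
    out.name = "NDR"
    return out


def active_enhancers(
    open_regions: IntervalSet, h3k27ac: IntervalSet, h3k4me1: IntervalSet
) -> IntervalSet:
    """Open regions overlapping (>= 1 bp) both H3K27ac and H3K4me1 peaks."""
    kept = [
        iv
        for iv in open_regions
        if overlap_stats(iv, h3k27ac)[0] > 0 and overlap_stats(iv, h3k4me1)[0] > 0
    ]
    return IntervalSet("enhancers", kept)


def conserved_open(
    reference_open: IntervalSet,
    other_open: list[IntervalSet],
    min_share: float = 0.8,
) -> IntervalSet:
    """Reference regions sharing more than ``min_share`` of their bases with
    the open set of at least one other cell line (strict inequality)."""
    if not (0 < min_share <= 1):
        raise ValueError("min_share must be in (0, 1]")
    import numpy as np

    keep = np.zeros(len(reference_open), dtype=bool)
    for other in other_open:
        keep |= coverage_fractions(reference_open, other) > min_share
    return IntervalSet(
        "conserved", [iv for iv, k in zip(reference_open, keep) if k]
    )


def differential_open(
    open_in: IntervalSet, open_other: IntervalSet, max_overlap: float = 0.2
) -> IntervalSet:
    """Regions of ``open_in`` overlapping ``open_other`` by less than
    ``max_overlap`` of their length: open in one condition, closed in the
    other.  Directionality is chosen by which set is passed as ``open_in``."""
    if not (0 <= max_overlap < 1):
        raise ValueError("max_overlap must be in [0, 1)")
    frac = coverage_fractions(open_in, open_other)
    return IntervalSet(
        "differential", [iv for iv, f in zip(open_in, frac) if f < max_overlap]
    )


def annotate_cell_line(
    cell_line: str,
    dnase_peaks: IntervalSet,
    genome: GenomeModel,
    fragment_sets: list[IntervalSet],
    h3k27ac: IntervalSet | None = None,
    h3k4me1: IntervalSet | None = None,
    flank: int = 1000,
    ndr_mode: str = "subtract",
) -> CellLineAnnotation:
    open_r = open_chromatin(dnase_peaks, genome, flank)
    ndr = ndr_regions(open_r, fragment_sets, mode=ndr_mode)
    if h3k27ac is not None and h3k4me1 is not None:
        enh = active_enhancers(open_r, h3k27ac, h3k4me1)
    else:
        enh = IntervalSet("enhancers")
    return CellLineAnnotation(
        cell_line,
        open_r,
        ndr,
        enh,
        provenance=dict(flank=flank, ndr_mode=ndr_mode),
    )
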