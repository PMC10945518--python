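"""Nucleosome dyad calling from mono-nucleosome MNase-seq fragments.

The mapping protocol: fragment midpoints of 146-148 bp fragments are counted
per genomic coordinate, smoothed with a triweight kernel (bandwidth h = 15 bp),
local maxima of the smoothed track at least 150 bp apart are located, and one
representative dyad per maximum is picked from the raw counts in a 60 bp
window.  Nucleosome regions (NRs) are the 147 bp spans dyad +/- 73 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomeModel, GenomicInterval, IntervalSet

#: default mono-nucleosome fragment-length window for dyad calling
DYAD_LEN_MIN, DYAD_LEN_MAX = 146, 148
#: wider window used for occupancy and NDR definition
OCC_LEN_MIN, OCC_LEN_MAX = 120, 180


@dataclass
class DyadCounts:
    """Sparse per-coordinate dyad counts d(j) on one chromosome."""

    chrom: str
    counts: dict[int, int]
    N: int

    def positions(self) -> np.ndarray:
        return np.array(sorted(self.counts), dtype=np.int64)


@dataclass
class SmoothedCounts:
    """Triweight-smoothed dyad counts D(i), stored densely on [0, N)."""

    chrom: str
    D: np.ndarray
    h: int


@dataclass
class DyadMap:
    """Representative dyads per chromosome: sorted (position, raw_count) lists."""

    dyads: dict[str, list[tuple[int, int]]]
    provenance: dict = field(default_factory=dict)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([p for p, _ in self.dyads.get(chrom, [])], dtype=np.int64)

    def n_dyads(self) -> int:
        return sum(len(v) for v in self.dyads.values())

    def all_positions(self) -> list[tuple[str, int]]:
        return [(c, p) for c, lst in sorted(self.dyads.items()) for p, _ in lst]


def triweight_kernel(u: np.ndarray, h: int) -> np.ndarray:
    """K(u) = (1 - (u/h)^2)^3 for |u| <= h, else 0."""
    u = np.asarray(u, dtype=float)
    k = (1.0 - (u / h) ** 2) ** 3
    return np.where(np.abs(u) <= h, k, 0.0)


def count_dyads(
    fragments: IntervalSet,
    chrom_length: dict[str, int],
    len_min: int = DYAD_LEN_MIN,
    len_max: int = DYAD_LEN_MAX,
) -> dict[str, DyadCounts]:
    """Count fragment midpoints per coordinate, keeping only fragments whose
    length falls in [len_min, len_max].  Midpoint = start + floor(len/2)."""
    if len_min > len_max:
        raise ValueError("len_min > len_max")
    per_chrom: dict[str, dict[int, int]] = {}
    for iv in fragments:
        flen = len(iv)
        if len_min <= flen <= len_max:
            mid = iv.start + flen // 2
            d = per_chrom.setdefault(iv.chrom, {})
            d[mid] = d.get(mid, 0) + 1
    return {
        chrom: DyadCounts(chrom, counts, chrom_length[chrom])
        for chrom, counts in per_chrom.items()
    }


def smooth_counts(raw: DyadCounts, h: int = 15) -> SmoothedCounts:
    """Kernel-smoothed dyad counts D(i) = (1/h) sum_j K(i-j) d(j).

    Computed by convolving the (dense) raw count track with the sampled
    kernel; identical to the double loop over all (i, j) pairs because K has
    bounded support |u| <= h.
    """
    if h < 1:
        raise ValueError("bandwidth h must be >= 1")
    dense = np.zeros(raw.N)
    for pos, c in raw.counts.items():
        dense[pos] = c
    kernel = triweight_kernel(np.arange(-h, h + 1), h) / h
    D = np.convolve(dense, kernel, mode="same")
    # convolution round-off can leave tiny negatives where D should be 0
    np.maximum(D, 0.0, out=D)
    return SmoothedCounts(raw.chrom, D, h)


def find_local_maxima(smoothed: SmoothedCounts, min_sep: int = 150) -> list[int]:
    """Local maxima of D at least ``min_sep`` bp apart.

    A plateau counts once, at its lowest coordinate.  When two maxima are
    closer than ``min_sep``, the one with the larger D survives (greedy by
    descending height; ties broken toward the lower coordinate).
    """
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    D = smoothed.D
    n = len(D)
    candidates: list[int] = []
    i = 0
    while i < n:
        if D[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and D[j + 1] == D[i]:
            j += 1
        left = D[i - 1] if i > 0 else 0.0
        right = D[j + 1] if j + 1 < n else 0.0
        if D[i] > left and D[i] > right:
            candidates.append(i)
        i = j + 1
    # enforce min_sep greedily by height
    order = sorted(candidates, key=lambda p: (-D[p], p))
    kept: list[int] = []
    kept_sorted: list[int] = []
    import bisect

    for p in order:
        k = bisect.bisect_left(kept_sorted, p)
        ok = True
        if k > 0 and p - kept_sorted[k - 1] < min_sep:
            ok = False
        if k < len(kept_sorted) and kept_sorted[k] - p < min_sep:
            ok = False
        if ok:
            bisect.insort(kept_sorted, p)
            kept.append(p)
    return sorted(kept)


def select_representative_dyads(
    raw_by_chrom: dict[str, DyadCounts],
    maxima_by_chrom: dict[str, list[int]],
    window: int = 60,
    provenance: dict | None = None,
) -> DyadMap:
    """One representative dyad per local maximum.

    Within the ``window`` bp window centered on each maximum m, the raw dyad
    position with the highest count wins; ties go to the position closest to
    m, then to the lower coordinate.  Windows without raw dyads contribute
    nothing; duplicate selections are collapsed.
    """
    half = window // 2
    dyads: dict[str, list[tuple[int, int]]] = {}
    for chrom, maxima in maxima_by_chrom.items():
        raw = raw_by_chrom.get(chrom)
        if raw is None or not maxima:
            continue
        positions = raw.positions()
        counts = np.array([raw.counts[int(p)] for p in positions])
        chosen: dict[int, int] = {}
        for m in maxima:
            lo = int(np.searchsorted(positions, m - half, side="left"))
            hi = int(np.searchsorted(positions, m + half, side="right"))
            if lo == hi:
                continue
            window_pos = positions[lo:hi]
            window_cnt = counts[lo:hi]
            best = min(
                range(len(window_pos)),
                key=lambda k: (-window_cnt[k], abs(int(window_pos[k]) - m), int(window_pos[k])),
            )
            chosen[int(window_pos[best])] = int(window_cnt[best])
        dyads[chrom] = sorted(chosen.items())
    return DyadMap(dyads, provenance or {})


def call_dyads(
    fragments: IntervalSet,
    genome: GenomeModel,
    len_min: int = DYAD_LEN_MIN,
    len_max: int = DYAD_LEN_MAX,
    h: int = 15,
    min_sep: int = 150,
    window: int = 60,
) -> DyadMap:
    """Full protocol: count -> smooth -> local maxima -> representatives."""
    raw = count_dyads(fragments, genome.chrom_sizes, len_min, len_max)
    maxima = {
        chrom: find_local_maxima(smooth_counts(rc, h), min_sep)
        for chrom, rc in raw.items()
    }
    prov = dict(len_min=len_min, len_max=len_max, h=h, min_sep=min_sep, window=window)
    return select_representative_dyads(raw, maxima, window, prov)


def nucleosome_regions(dyads: DyadMap, genome: GenomeModel) -> IntervalSet:
    """147 bp nucleosome regions [d-73, d+74), clipped to chromosome bounds."""
    out = []
    for chrom, lst in sorted(dyads.dyads.items()):
        n = genome.chrom_sizes[chrom]
        for pos, _ in lst:
            s, e = max(pos - 73, 0), min(pos + 74, n)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
    return IntervalSet("NR", out)


def fragment_coverage(
    fragments: IntervalSet,
    chrom_sizes: dict[str, int],
    len_min: int = OCC_LEN_MIN,
    len_max: int = OCC_LEN_MAX,
) -> dict[str, np.ndarray]:
    """Dense per-base fragment coverage per chromosome, after length filter."""
    cov = {c: np.zeros(n + 1) for c, n in chrom_sizes.items()}
    for iv in fragments:
        if len_min <= len(iv) <= len_max and iv.chrom in cov:
            cov[iv.chrom][iv.start] += 1
            cov[iv.chrom][iv.end] -= 1
    return {c: np.cumsum(a)[:-1] for c, a in cov.items()}


def occupancy_profile(
    fragments: IntervalSet,
    dyads: DyadMap,
    flank: int = 400,
    len_min: int = OCC_LEN_MIN,
    len_max: int = OCC_LEN_MAX,
    chrom_sizes: dict[str, int] | None = None,
    mode: str = "coverage",
) -> np.ndarray:
    """Mean nucleosome occupancy at offsets -flank..+flank around dyads.

    ``mode='coverage'`` (default): occupancy is the mean number of
    size-filtered fragments covering each position, per dyad.
    ``mode='dyad_density'``: mean triweight-smoothed dyad count instead —
    kept as an alternative occupancy estimator.
    """
    if dyads.n_dyads() == 0:
        raise ValueError("no dyads")
    if chrom_sizes is None:
        maxend: dict[str, int] = {}
        for iv in fragments:
            maxend[iv.chrom] = max(maxend.get(iv.chrom, 0), iv.end)
        for chrom, lst in dyads.dyads.items():
            if lst:
                maxend[chrom] = max(maxend.get(chrom, 0), lst[-1][0] + flank + 1)
        chrom_sizes = maxend
    if mode == "coverage":
        tracks = fragment_coverage(fragments, chrom_sizes, len_min, len_max)
    elif mode == "dyad_density":
        raw = count_dyads(fragments, chrom_sizes, len_min, len_max)
        tracks = {c: smooth_counts(rc).D for c, rc in raw.items()}
    else:
        raise ValueError(f"unknown occupancy mode {mode!r}")
    acc = np.zeros(2 * flank + 1)
    n = 0
    for chrom, lst in dyads.dyads.items():
        track = tracks.get(chrom)
        if track is None:
            track = np.zeros(chrom_sizes.get(chrom, 0))
        # pad so every dyad window is in bounds
        padded = np.concatenate([np.zeros(flank), track, np.zeros(flank)])
        for pos, _ in lst:
            acc += padded[pos : pos + 2 * flank + 1]
            n += 1
    return acc / n
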