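"""Genomic interval data model, BED/narrowPeak/FASTA I/O, and interval arithmetic.

All coordinates are 0-based half-open (BED convention). Every region set used
downstream (nucleosome regions, NDRs, peaks, fragments, motif hits) is carried
as an :class:`IntervalSet` of :class:`GenomicInterval` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np


class ParseError(ValueError):
    """Raised for malformed interval records; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). ``summit`` holds
    the narrowPeak point-source offset relative to ``start`` (-1 if absent).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    summit: int = -1

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Peak center: the summit position if recorded, else the midpoint."""
        if self.summit >= 0:
            return self.start + self.summit
        return (self.start + self.end) // 2


@dataclass
class IntervalSet:
    """A named list of genomic intervals.

    :meth:`canonicalize` sorts by (chrom, start) and merges overlapping or
    bookended intervals; region annotations are kept canonical, fragment and
    hit sets are not (multiplicity matters there).
    """

    name: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out = {}
        for chrom, ivs in self.by_chrom().items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            out[chrom] = (starts[order], ends[order])
        return out

    def canonicalize(self) -> "IntervalSet":
        """Sorted, merged copy (union of covered bases)."""
        merged: list[GenomicInterval] = []
        for chrom in sorted(self.by_chrom()):
            ivs = sorted(self.by_chrom()[chrom], key=lambda iv: (iv.start, iv.end))
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(self.name, merged)


@dataclass
class GenomeModel:
    """Chromosome sizes plus (optionally) the DNA sequence per chromosome."""

    chrom_sizes: dict[str, int]
    sequence: Optional[dict[str, str]] = None

    def require_sequence(self) -> dict[str, str]:
        if self.sequence is None:
            raise ValueError("genome sequence required but not loaded")
        return self.sequence

    def check(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(f"{iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length")


# ---------------------------------------------------------------------------
# I/O


def parse_intervals(path, format: str = "bed") -> IntervalSet:
    """Read a BED3+, narrowPeak, or fragment-BED file into an IntervalSet.

    ``format`` is one of ``bed``, ``narrowpeak``, ``fragments``.  Coordinates
    are taken verbatim (BED files are already 0-based half-open).  narrowPeak
    requires 10 tab-separated columns and retains the summit offset.
    Malformed lines raise :class:`ParseError` naming the line number.
    """
    if format not in ("bed", "narrowpeak", "fragments"):
        raise ValueError(f"unknown format {format!r}")
    min_fields = 10 if format == "narrowpeak" else 3
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ParseError(
                    f"expected >= {min_fields} fields at line {lineno}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate at line {lineno}") from exc
            if start >= end:
                raise ParseError(f"start >= end at line {lineno}")
            if start < 0:
                raise ParseError(f"negative start at line {lineno}")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            summit = -1
            if format == "narrowpeak":
                try:
                    summit = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"non-integer summit at line {lineno}") from exc
            intervals.append(GenomicInterval(fields[0], start, end, strand, summit))
    return IntervalSet(name=str(path), intervals=intervals)


def write_bed(ivset: IntervalSet, path, scores: Optional[Iterable] = None) -> None:
    """Write BED3 (or BED6 when scores are given; name column = set name)."""
    with open(path, "w") as fh:
        if scores is None:
            for iv in ivset:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, sc in zip(ivset, scores):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ivset.name or '.'}\t{sc}\t{iv.strand}\n"
                )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"expected 2 columns at line {lineno}")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an in-memory chrom -> sequence map (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def genome_from_files(chrom_sizes_path=None, fasta_path=None) -> GenomeModel:
    if fasta_path is not None:
        seq = read_fasta(fasta_path)
        sizes = (
            read_chrom_sizes(chrom_sizes_path)
            if chrom_sizes_path
            else {c: len(s) for c, s in seq.items()}
        )
        return GenomeModel(sizes, seq)
    if chrom_sizes_path is None:
        raise ValueError("need chrom sizes or FASTA")
    return GenomeModel(read_chrom_sizes(chrom_sizes_path))


# ---------------------------------------------------------------------------
# Interval arithmetic


def _covered_segments(
    q_start: int, q_end: int, starts: np.ndarray, ends: np.ndarray
) -> list[tuple[int, int]]:
    """Sub-segments of [q_start, q_end) covered by a disjoint sorted target set.

    ``starts``/``ends`` must come from a canonicalized (merged) set, so both
    arrays are sorted and the intervals are pairwise disjoint.
    """
    if len(starts) == 0:
        return []
    lo = int(np.searchsorted(ends, q_start, side="right"))
    hi = int(np.searchsorted(starts, q_end, side="left"))
    segs: list[tuple[int, int]] = []
    for i in range(lo, hi):
        s = max(int(starts[i]), q_start)
        e = min(int(ends[i]), q_end)
        if s < e:
            segs.append((s, e))
    return segs


def overlap_stats(query: GenomicInterval, targets: IntervalSet) -> tuple[int, float]:
    """Bases of ``query`` covered by >=1 target, and that count as a fraction
    of the query length.  ``targets`` need not be canonical; it is merged first.
    """
    if len(targets) == 0:
        return 0, 0.0
    arrays = targets.canonicalize().chrom_arrays()
    if query.chrom not in arrays:
        return 0, 0.0
    starts, ends = arrays[query.chrom]
    segs = _covered_segments(query.start, query.end, starts, ends)
    bp = sum(e - s for s, e in segs)
    return bp, bp / len(query)


def coverage_fractions(queries: IntervalSet, targets: IntervalSet) -> np.ndarray:
    """Per-query covered fraction against a (merged) target set; vectorized
    driver used by the region-annotation filters."""
    out = np.zeros(len(queries))
    if len(targets) == 0:
        return out
    arrays = targets.canonicalize().chrom_arrays()
    for i, iv in enumerate(queries):
        if iv.chrom not in arrays:
            continue
        starts, ends = arrays[iv.chrom]
        segs = _covered_segments(iv.start, iv.end, starts, ends)
        out[i] = sum(e - s for s, e in segs) / len(iv)
    return out


def subtract_coverage(regions: IntervalSet, covers: IntervalSet) -> IntervalSet:
    """Maximal sub-intervals of each region not covered by any cover interval.

    The output order follows the input regions; covered bases plus returned
    bases partition each region exactly.
    """
    arrays = covers.canonicalize().chrom_arrays() if len(covers) else {}
    out: list[GenomicInterval] = []
    for iv in regions:
        if iv.chrom not in arrays:
            out.append(iv)
            continue
        starts, ends = arrays[iv.chrom]
        pos = iv.start
        for s, e in _covered_segments(iv.start, iv.end, starts, ends):
            if s > pos:
                out.append(GenomicInterval(iv.chrom, pos, s))
            pos = e
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return IntervalSet(regions.name, out)


def intersect(regions: IntervalSet, mask: IntervalSet) -> IntervalSet:
    """Sub-intervals of each region covered by the (merged) mask set."""
    if len(mask) == 0:
        return IntervalSet(regions.name)
    arrays = mask.canonicalize().chrom_arrays()
    out: list[GenomicInterval] = []
    for iv in regions:
        if iv.chrom not in arrays:
            continue
        starts, ends = arrays[iv.chrom]
        for s, e in _covered_segments(iv.start, iv.end, starts, ends):
            out.append(GenomicInterval(iv.chrom, s, e))
    return IntervalSet(regions.name, out)


def clip_to_genome(ivset: IntervalSet, genome: GenomeModel) -> IntervalSet:
    """Clip every interval to [0, chrom length); drop intervals that vanish."""
    out: list[GenomicInterval] = []
    for iv in ivset:
        if iv.chrom not in genome.chrom_sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        n = genome.chrom_sizes[iv.chrom]
        s, e = max(iv.start, 0), min(iv.end, n)
        if s < e:
            out.append(GenomicInterval(iv.chrom, s, e, iv.strand, iv.summit))
    return IntervalSet(ivset.name, out)


def clip_span(chrom: str, start: int, end: int, genome: GenomeModel) -> Optional[GenomicInterval]:
    """Clip a raw (possibly out-of-bounds) span; None if nothing remains."""
    n = genome.chrom_sizes[chrom]
    s, e = max(start, 0), min(end, n)
    if s < e:
        return GenomicInterval(chrom, s, e)
    return None
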