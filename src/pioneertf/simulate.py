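"""Self-contained synthetic fixture: genome, nucleosome landscape, fragments,
peaks, motifs, expression, and ground truth.

The generator emulates, at desk scale, the statistical structure the analysis
assumes: a genome tiled with nucleosomes at known dyads emitting ~147 bp
mono-nucleosome fragments with positional jitter; open-chromatin regions per
cell line, each with a central nucleosome-free gap (the true NDR); and TF
ChIP peak sets whose motif instances are embedded into the genome sequence
preferentially on nucleosome regions (pioneers) or in nucleosome-depleted
gaps (canonical TFs).  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomeModel, GenomicInterval, IntervalSet, write_bed, write_fasta
from .motifs import BASES, PFM, write_jaspar

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic landscape.

    The defaults define the standard study conditions: a 1 Mb single
    chromosome, nucleosome spacing 200 +/- 20 bp, 30 fragments per nucleosome
    (Poisson) with lengths 147 +/- 5 bp and 10 bp dyad jitter, two cell
    lines, half the genome in open regions (so nucleosomal and
    nucleosome-depleted compartments are of comparable size at toy scale),
    40 TFs of which 25% are pioneers, and motif-placement NR biases of 0.7
    (pioneer) versus 0.1 (canonical).
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    nucleosome_spacing_mean: float = 200.0
    nucleosome_spacing_sd: float = 20.0
    fragments_per_nucleosome: float = 30.0
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 5.0
    fragment_length_bounds: tuple[int, int] = (100, 200)
    dyad_jitter_sd: float = 10.0
    n_tfs: int = 40
    pioneer_fraction: float = 0.25
    pioneer_nr_bias: float = 0.7
    canonical_nr_bias: float = 0.1
    instances_per_tf: int = 100
    motif_length: int = 8
    n_cell_lines: int = 2
    open_fraction: float = 0.5
    ndr_gap: int = 1600  # nucleosome-free core of each open region, bp
    open_region_halfwidth: int = 1000
    p_differential: float = 0.5  # open in line A only, closed in the others
    pioneer_host_regions: str = "differential"  # or "any"
    shl_target: dict = field(default_factory=dict)  # tf -> (shl_lo, shl_hi)
    shl_signal_fraction: float = 0.75  # 3:1 signal to uniform background
    low_expression_fraction: float = 0.1
    histone_mark_prob: float = 0.6
    ww_period: Optional[int] = None  # plant periodic WW dinucleotides

    def validate(self) -> None:
        if self.nucleosome_spacing_mean < 147:
            raise ValueError("nucleosome spacing below the 147 bp footprint")
        if self.motif_length > 139:
            raise ValueError("motif longer than a nucleosome region")
        if not (0 <= self.pioneer_nr_bias <= 1 and 0 <= self.canonical_nr_bias <= 1):
            raise ValueError("NR biases must be probabilities")


@dataclass
class TruthTable:
    """Ground truth of everything planted."""

    dyads: dict[str, dict[str, list[int]]]  # cell line -> chrom -> positions
    region_labels: list[tuple[GenomicInterval, str]]  # open regions of line A
    tf_labels: dict[str, str]  # tf -> pioneer | canonical
    tf_shl: dict[str, tuple[float, float]]
    instances: list[dict]  # tf, chrom, start, end, strand, host, region


@dataclass
class Bundle:
    """One simulated data set, in memory."""

    config: SimulationConfig
    genome: GenomeModel
    truth: TruthTable
    cell_lines: list[str]
    fragments: dict[str, IntervalSet]  # per cell line
    dnase_peaks: dict[str, IntervalSet]  # per cell line
    h3k27ac: dict[str, IntervalSet]
    h3k4me1: dict[str, IntervalSet]
    pfms: list[PFM]
    tf_peaks: dict[str, IntervalSet]  # per TF (cell line A)
    rpkm: pd.DataFrame


def _plant_open_regions(cfg: SimulationConfig, rng, chrom: str, n: int):
    """Evenly spaced open regions with per-region conserved/differential labels."""
    width = 2 * cfg.open_region_halfwidth + 1
    if cfg.open_fraction <= 0:
        return []
    period = int(round(width / cfg.open_fraction))
    regions = []
    c = period // 2
    while c + cfg.open_region_halfwidth + 200 < n:
        label = "differential" if rng.random() < cfg.p_differential else "conserved"
        iv = GenomicInterval(
            chrom, c - cfg.open_region_halfwidth, c + cfg.open_region_halfwidth + 1
        )
        regions.append((iv, label))
        c += period
    return regions


def _gap_of(iv: GenomicInterval, cfg: SimulationConfig) -> tuple[int, int]:
    c = (iv.start + iv.end) // 2
    return c - cfg.ndr_gap // 2, c + cfg.ndr_gap // 2


def _plant_dyads(cfg: SimulationConfig, rng, n: int, gaps: list[tuple[int, int]]):
    """Nucleosome chain with Gaussian spacing, skipping nucleosome-free gaps."""
    gaps = sorted(gaps)
    dyads = []
    pos = 100.0
    while pos < n - 100:
        d = int(round(pos))
        # exclude dyads whose footprint would reach into a gap
        in_gap = any(g0 - 73 <= d < g1 + 73 for g0, g1 in gaps)
        if not in_gap:
            dyads.append(d)
        step = rng.normal(cfg.nucleosome_spacing_mean, cfg.nucleosome_spacing_sd)
        pos += max(step, 150.0)
    return dyads


def _emit_fragments(cfg: SimulationConfig, rng, chrom: str, dyads: list[int], n: int):
    lo, hi = cfg.fragment_length_bounds
    out = []
    for d in dyads:
        k = rng.poisson(cfg.fragments_per_nucleosome)
        if k == 0:
            continue
        lengths = np.clip(
            np.rint(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, k)),
            lo,
            hi,
        ).astype(int)
        mids = d + np.rint(rng.normal(0.0, cfg.dyad_jitter_sd, k)).astype(int)
        starts = mids - lengths // 2
        ends = starts + lengths
        for s, e in zip(starts, ends):
            if 0 <= s < e <= n:
                out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


class _Occupied:
    """Tracks motif-occupied spans so planted instances never overlap."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def reserve(self, chrom: str, start: int, end: int) -> bool:
        lst = self.spans.setdefault(chrom, [])
        for s, e in lst:
            if start < e and s < end:
                return False
        lst.append((start, end))
        return True


def _random_pfm(rng, tf: str, L: int, dominant: int = 85, minor: int = 5) -> PFM:
    consensus = rng.integers(0, 4, L)
    mat = np.full((4, L), minor, dtype=float)
    mat[consensus, np.arange(L)] = dominant
    return PFM(tf, mat)


def simulate_landscape(cfg: SimulationConfig):
    """Genome + nucleosome landscape + per-cell-line fragments (no TFs yet)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    sizes = {c: cfg.genome_length for c in chroms}
    sequence = {
        c: "".join(np.array(list(BASES))[rng.integers(0, 4, cfg.genome_length)])
        for c in chroms
    }
    genome = GenomeModel(sizes, sequence)

    cell_lines = [chr(ord("A") + i) for i in range(cfg.n_cell_lines)]
    region_labels: list[tuple[GenomicInterval, str]] = []
    truth_dyads: dict[str, dict[str, list[int]]] = {cl: {} for cl in cell_lines}
    fragments: dict[str, list[GenomicInterval]] = {cl: [] for cl in cell_lines}
    dnase: dict[str, list[GenomicInterval]] = {cl: [] for cl in cell_lines}

    for chrom in chroms:
        regs = _plant_open_regions(cfg, rng, chrom, cfg.genome_length)
        region_labels.extend(regs)
        for cl in cell_lines:
            if cl == "A":
                mine = [iv for iv, _ in regs]
            else:
                mine = [iv for iv, lab in regs if lab == "conserved"]
            gaps = [_gap_of(iv, cfg) for iv in mine]
            dyads = _plant_dyads(cfg, rng, cfg.genome_length, gaps)
            truth_dyads[cl][chrom] = dyads
            fragments[cl].extend(
                _emit_fragments(cfg, rng, chrom, dyads, cfg.genome_length)
            )
            for iv in mine:
                c = (iv.start + iv.end) // 2
                dnase[cl].append(
                    GenomicInterval(chrom, c - 100, c + 101, summit=100)
                )
        if cfg.ww_period:
            seq = list(sequence[chrom])
            w = "AT"
            for d in truth_dyads["A"][chrom]:
                for off in range(-70, 71, cfg.ww_period):
                    i = d + off
                    if 0 <= i + 1 < cfg.genome_length:
                        seq[i] = w[int(rng.integers(0, 2))]
                        seq[i + 1] = w[int(rng.integers(0, 2))]
            sequence[chrom] = "".join(seq)

    truth = TruthTable(truth_dyads, region_labels, {}, {}, [])
    return genome, truth, cell_lines, fragments, dnase, rng


def _dyads_for_planting(cfg, truth, chrom):
    """(all dyads, dyads inside differentially open regions) for line A."""
    dyads = np.array(truth.dyads["A"][chrom])
    diff = [iv for iv, lab in truth.region_labels
            if lab == "differential" and iv.chrom == chrom]
    in_diff = np.zeros(len(dyads), dtype=bool)
    for iv in diff:
        in_diff |= (dyads >= iv.start) & (dyads < iv.end)
    return dyads, dyads[in_diff]


def simulate_tfs(cfg: SimulationConfig, genome, truth, rng):
    """Plant per-TF motif instances into the genome; emit PFMs, peaks, RPKM."""
    chroms = list(genome.chrom_sizes)
    n_pioneer = int(round(cfg.n_tfs * cfg.pioneer_fraction))
    tf_names = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    labels = {
        tf: ("pioneer" if i < n_pioneer else "canonical")
        for i, tf in enumerate(tf_names)
    }
    seqs = {c: list(genome.sequence[c]) for c in chroms}
    occupied = _Occupied()
    pfms, tf_peaks = [], {}
    all_dyads = {c: _dyads_for_planting(cfg, truth, c)[0] for c in chroms}
    diff_dyads = {c: _dyads_for_planting(cfg, truth, c)[1] for c in chroms}
    gap_list = {
        c: [
            _gap_of(iv, cfg)
            for iv, _ in truth.region_labels
            if iv.chrom == c
        ]
        for c in chroms
    }
    gap_label = {
        c: [lab for iv, lab in truth.region_labels if iv.chrom == c]
        for c in chroms
    }
    L = cfg.motif_length

    for tf in tf_names:
        pfm = _random_pfm(rng, tf, L)
        pfms.append(pfm)
        motif = pfm.consensus()
        bias = cfg.pioneer_nr_bias if labels[tf] == "pioneer" else cfg.canonical_nr_bias
        shl = cfg.shl_target.get(tf)
        if shl is not None:
            truth.tf_shl[tf] = tuple(shl)
        peaks = []
        for _ in range(cfg.instances_per_tf):
            host = "NR" if rng.random() < bias else "NDR"
            for _attempt in range(200):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                if host == "NR":
                    pool = (
                        diff_dyads[chrom]
                        if labels[tf] == "pioneer"
                        and cfg.pioneer_host_regions == "differential"
                        and len(diff_dyads[chrom])
                        else all_dyads[chrom]
                    )
                    if len(pool) == 0:
                        continue
                    d = int(pool[int(rng.integers(0, len(pool)))])
                    if shl is not None and rng.random() < cfg.shl_signal_fraction:
                        off = _shl_offset(rng, shl, L)
                    else:
                        off = int(rng.integers(-73, 74 - L))
                    start = d + off
                    region = "NR"
                else:
                    gaps = gap_list[chrom]
                    if not gaps:
                        continue
                    gi = int(rng.integers(0, len(gaps)))
                    g0, g1 = gaps[gi]
                    margin = 150
                    if g1 - margin - L <= g0 + margin:
                        continue
                    start = int(rng.integers(g0 + margin, g1 - margin - L))
                    region = gap_label[chrom][gi]
                end = start + L
                if start < 0 or end > genome.chrom_sizes[chrom]:
                    continue
                if not occupied.reserve(chrom, start - 1, end + 1):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                planted = motif if strand == "+" else motif.translate(_COMPLEMENT)[::-1]
                seqs[chrom][start:end] = list(planted)
                truth.instances.append(
                    dict(
                        tf=tf, chrom=chrom, start=start, end=end,
                        strand=strand, host=host, region=region,
                    )
                )
                c = start + L // 2
                peaks.append(
                    GenomicInterval(
                        chrom,
                        max(c - 100, 0),
                        min(c + 101, genome.chrom_sizes[chrom]),
                        summit=min(100, c),
                    )
                )
                break
        tf_peaks[tf] = IntervalSet(tf, peaks)
    genome.sequence = {c: "".join(s) for c, s in seqs.items()}
    truth.tf_labels = labels

    rows = []
    cell_lines = [chr(ord("A") + i) for i in range(cfg.n_cell_lines)]
    for tf in tf_names:
        low = rng.random() < cfg.low_expression_fraction
        for cl in cell_lines:
            rpkm = rng.uniform(0.5, 9.5) if low else rng.uniform(10.0, 100.0)
            rows.append(dict(tf=tf, cell_line=cl, rpkm=round(float(rpkm), 3)))
    return pfms, tf_peaks, pd.DataFrame(rows)


def _shl_offset(rng, shl: tuple[float, float], L: int) -> int:
    """Motif start offset so that all motif bases fall inside the SHL window
    (on a randomly chosen nucleosome half)."""
    from .profiles import BP_PER_SHL

    lo_bp = int(np.floor(shl[0] * BP_PER_SHL + 0.5))
    hi_bp = int(np.floor(shl[1] * BP_PER_SHL + 0.5))
    if hi_bp - lo_bp + 1 < L:
        lo_start, hi_start = lo_bp, lo_bp  # degenerate window
    else:
        lo_start, hi_start = lo_bp, hi_bp - L + 1
    start = int(rng.integers(lo_start, hi_start + 1))
    if rng.random() < 0.5:
        start = -(start + L - 1)
    return start


def _histone_marks(cfg, truth, rng):
    """narrowPeak proxies around a random subset of line-A open regions."""
    h27, h4 = [], []
    for iv, _ in truth.region_labels:
        c = (iv.start + iv.end) // 2
        if rng.random() < cfg.histone_mark_prob:
            h27.append(GenomicInterval(iv.chrom, c - 150, c + 151, summit=150))
        if rng.random() < cfg.histone_mark_prob:
            h4.append(GenomicInterval(iv.chrom, c - 150, c + 151, summit=150))
    return IntervalSet("H3K27ac", h27), IntervalSet("H3K4me1", h4)


def simulate_bundle(cfg: SimulationConfig) -> Bundle:
    """Full fixture: landscape + TFs + histone marks + expression table."""
    genome, truth, cell_lines, fragments, dnase, rng = simulate_landscape(cfg)
    if cfg.n_tfs > 0:
        pfms, tf_peaks, rpkm = simulate_tfs(cfg, genome, truth, rng)
    else:
        pfms, tf_peaks = [], {}
        rpkm = pd.DataFrame(columns=["tf", "cell_line", "rpkm"])
    h27, h4 = _histone_marks(cfg, truth, rng)
    return Bundle(
        config=cfg,
        genome=genome,
        truth=truth,
        cell_lines=cell_lines,
        fragments={cl: IntervalSet(f"frag_{cl}", fr) for cl, fr in fragments.items()},
        dnase_peaks={cl: IntervalSet(f"dnase_{cl}", pk) for cl, pk in dnase.items()},
        h3k27ac={"A": h27},
        h3k4me1={"A": h4},
        pfms=pfms,
        tf_peaks=tf_peaks,
        rpkm=rpkm,
    )


def write_bundle(bundle: Bundle, out_dir) -> dict:
    """Write the bundle as plain-text files; returns the manifest
    (file -> sha256 of contents)."""
    os.makedirs(out_dir, exist_ok=True)
    paths: list[str] = []

    def reg(name: str) -> str:
        paths.append(name)
        return os.path.join(out_dir, name)

    write_fasta(bundle.genome.sequence, reg("genome.fa"))
    with open(reg("genome.chrom.sizes"), "w") as fh:
        for c, n in bundle.genome.chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
    for cl, frags in bundle.fragments.items():
        write_bed(frags, reg(f"fragments_{cl}.bed"))
    for cl, peaks in bundle.dnase_peaks.items():
        _write_narrowpeak(peaks, reg(f"dnase_{cl}.narrowPeak"))
    _write_narrowpeak(bundle.h3k27ac["A"], reg("h3k27ac_A.narrowPeak"))
    _write_narrowpeak(bundle.h3k4me1["A"], reg("h3k4me1_A.narrowPeak"))
    write_jaspar(bundle.pfms, reg("motifs.jaspar"))
    for tf, peaks in bundle.tf_peaks.items():
        _write_narrowpeak(peaks, reg(f"chip_{tf}.narrowPeak"))
    bundle.rpkm.to_csv(reg("rpkm.tsv"), sep="\t", index=False)
    with open(reg("truth_tf_labels.tsv"), "w") as fh:
        fh.write("tf\tlabel\n")
        for tf, lab in bundle.truth.tf_labels.items():
            fh.write(f"{tf}\t{lab}\n")
    with open(reg("truth_dyads_A.tsv"), "w") as fh:
        fh.write("chrom\tposition\n")
        for chrom, lst in bundle.truth.dyads["A"].items():
            for d in lst:
                fh.write(f"{chrom}\t{d}\n")
    with open(reg("truth_instances.tsv"), "w") as fh:
        fh.write("tf\tchrom\tstart\tend\tstrand\thost\tregion\n")
        for ins in bundle.truth.instances:
            fh.write(
                "\t".join(
                    str(ins[k])
                    for k in ("tf", "chrom", "start", "end", "strand", "host", "region")
                )
                + "\n"
            )
    manifest = {}
    for name in paths:
        with open(os.path.join(out_dir, name), "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_narrowpeak(ivset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in ivset:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ivset.name or '.'}\t0\t.\t0\t-1\t-1\t{iv.summit}\n"
            )


def template_half_profiles(
    n: int = 60, seed: int = 0, noise_sd: float = 0.05, n_templates: int = 3
):
    """Synthetic 61-point half-profiles drawn from template binding modes.

    Templates are Gaussian bumps at the DNA end (offset 60), the dyad
    (offset 0), and SHL 3 (offset ~31); each draw adds Gaussian noise and is
    re-normalized to [0, 1].  Returns (profiles, template_labels).
    """
    rng = np.random.default_rng(seed)
    centers = [60.0, 0.0, 31.0][:n_templates]
    offs = np.arange(61, dtype=float)
    X = np.empty((n, 61))
    labels = np.empty(n, dtype=int)
    for i in range(n):
        t = i % n_templates
        base = np.exp(-0.5 * ((offs - centers[t]) / 8.0) ** 2)
        prof = base + rng.normal(0.0, noise_sd, 61)
        prof -= prof.min()
        if prof.max() > 0:
            prof /= prof.max()
        X[i] = prof
        labels[i] = t
    return X, labels
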