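"""End-to-end orchestration of the pioneer-TF analysis.

``run_enrichment`` executes dyad calling -> region annotation -> motif
scanning -> NR/NDR enrichment -> expression-filtered ranking (plus classifier
metrics when truth labels are available); ``run_profiles`` builds
dyad-anchored motif profiles, occupancy correlations, end/dyad ratios, and
the profile clustering.  Both are deterministic functions of (inputs, seed)
and echo every threshold into a provenance manifest.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering as clustering_mod
from . import enrichment as enr
from .dyads import DyadMap, call_dyads, nucleosome_regions, occupancy_profile
from .intervals import GenomicInterval, IntervalSet, intersect
from .motifs import build_pwm, scan
from .profiles import (
    MotifProfile,
    build_profile,
    end_dyad_ratio,
    occupancy_correlation,
    symmetry_pcc,
)
from .regions import annotate_cell_line, conserved_open, differential_open
from .simulate import Bundle

log = logging.getLogger("pioneertf")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """All pipeline parameters, with their standard defaults."""

    mode: str = "all_open"  # or "differential"
    primary_cell_line: str = "A"
    other_cell_line: str = "B"
    bandwidth: int = 15
    min_sep: int = 150
    rep_window: int = 60
    dyad_len: tuple[int, int] = (146, 148)
    occ_len: tuple[int, int] = (120, 180)
    open_flank: int = 1000
    ndr_mode: str = "subtract"
    min_share: float = 0.8
    max_overlap: float = 0.2
    p_threshold: float = 1e-4
    pseudocount: float = 0.1
    rpkm_min: float = 10.0
    q_max: float = 0.05
    profile_flank: int = 1000
    occupancy_flank: int = 400
    k: int = 6
    max_sil: float = 0.25
    min_nr_bp: int = 500
    min_sym_pcc: float = 0.4
    perplexity: float = 30.0
    use_embedding: bool = True
    seed: int = 1234

    def manifest(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _dyads_in_regions(dyads: DyadMap, regions: IntervalSet) -> DyadMap:
    """Dyads whose position lies inside one of the regions."""
    arrays = regions.canonicalize().chrom_arrays()
    out = {}
    for chrom, lst in dyads.dyads.items():
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        kept = []
        for pos, cnt in lst:
            k = int(np.searchsorted(starts, pos, side="right")) - 1
            if k >= 0 and pos < ends[k]:
                kept.append((pos, cnt))
        if kept:
            out[chrom] = kept
    return DyadMap(out, dyads.provenance)


def _call_and_annotate(bundle: Bundle, cfg: RunConfig):
    cl = cfg.primary_cell_line
    t0 = time.time()
    dyads = call_dyads(
        bundle.fragments[cl],
        bundle.genome,
        *cfg.dyad_len,
        h=cfg.bandwidth,
        min_sep=cfg.min_sep,
        window=cfg.rep_window,
    )
    log.info("dyads: %d called in %.1fs", dyads.n_dyads(), time.time() - t0)
    ann = annotate_cell_line(
        cl,
        bundle.dnase_peaks[cl],
        bundle.genome,
        [bundle.fragments[cl]],
        bundle.h3k27ac.get(cl),
        bundle.h3k4me1.get(cl),
        flank=cfg.open_flank,
        ndr_mode=cfg.ndr_mode,
    )
    log.info(
        "regions: %d open (%d bp), %d NDR (%d bp)",
        len(ann.open_regions), ann.open_regions.total_bp(),
        len(ann.ndr_regions), ann.ndr_regions.total_bp(),
    )
    return dyads, ann


def _select_regions(bundle: Bundle, cfg: RunConfig, dyads: DyadMap, ann):
    """(NR set, NDR set) for the configured analysis mode."""
    nr_all = nucleosome_regions(dyads, bundle.genome)
    if cfg.mode == "all_open":
        return nr_all, ann.ndr_regions, dyads
    if cfg.mode != "differential":
        raise ValueError(f"unknown mode {cfg.mode!r}")
    other = cfg.other_cell_line
    if other not in bundle.dnase_peaks:
        raise ValueError("differential mode needs a second cell line")
    from .regions import open_chromatin

    other_open = open_chromatin(
        bundle.dnase_peaks[other], bundle.genome, cfg.open_flank
    )
    conserved = conserved_open(ann.open_regions, [other_open], cfg.min_share)
    differential = differential_open(ann.open_regions, other_open, cfg.max_overlap)
    dyads_diff = _dyads_in_regions(dyads, differential)
    nr_diff = nucleosome_regions(dyads_diff, bundle.genome)
    ndr_cons = intersect(ann.ndr_regions, conserved)
    if len(nr_diff) == 0 or len(ndr_cons) == 0:
        raise ValueError("differential mode produced empty NR or NDR set")
    return nr_diff, ndr_cons, dyads


def scan_all_tfs(bundle: Bundle, cfg: RunConfig) -> dict[str, list]:
    """FIMO-style scan of every TF's merged peak set; hits per TF."""
    hits = {}
    for pfm in bundle.pfms:
        pwm = build_pwm(pfm, pseudocount=cfg.pseudocount)
        peaks = bundle.tf_peaks[pfm.tf_name].canonicalize()
        hits[pfm.tf_name] = scan(pwm, peaks, bundle.genome, cfg.p_threshold)
    log.info("scan: %d TFs, %d hits total", len(hits), sum(map(len, hits.values())))
    return hits


def run_enrichment(bundle: Bundle, cfg: RunConfig | None = None) -> dict:
    """Ranked pioneer-candidate table (+ metrics when truth labels exist)."""
    cfg = cfg or RunConfig()
    dyads, ann = _call_and_annotate(bundle, cfg)
    nr, ndr, dyads = _select_regions(bundle, cfg, dyads, ann)
    hits = scan_all_tfs(bundle, cfg)
    records = [
        enr.score_tf(tf, cfg.primary_cell_line, h, nr, ndr, mode=cfg.mode)
        for tf, h in hits.items()
    ]
    enr.attach_fdr(records)
    table = enr.rank_candidates(records, bundle.rpkm, cfg.rpkm_min, cfg.q_max)
    out = dict(table=table, records=records, dyads=dyads, annotation=ann,
               nr=nr, ndr=ndr, hits=hits, provenance=cfg.manifest())
    if bundle.truth.tf_labels:
        from .metrics import evaluate_scores

        sub = table[table["expressed"] == True]  # noqa: E712
        labels = [bundle.truth.tf_labels[tf] == "pioneer" for tf in sub["tf"]]
        if any(labels) and not all(labels):
            out["metrics"] = evaluate_scores(sub["score"].to_numpy(), labels)
            log.info("metrics: %s", out["metrics"])
    return out


def run_profiles(
    bundle: Bundle,
    cfg: RunConfig | None = None,
    dyads: DyadMap | None = None,
    hits: dict[str, list] | None = None,
) -> dict:
    """Motif profiles, occupancy correlations, R_end/dyad, and clustering."""
    cfg = cfg or RunConfig()
    cl = cfg.primary_cell_line
    if dyads is None:
        dyads = call_dyads(
            bundle.fragments[cl],
            bundle.genome,
            *cfg.dyad_len,
            h=cfg.bandwidth,
            min_sep=cfg.min_sep,
            window=cfg.rep_window,
        )
    if hits is None:
        hits = scan_all_tfs(bundle, cfg)
    occ = occupancy_profile(
        bundle.fragments[cl], dyads, cfg.occupancy_flank, *cfg.occ_len,
        chrom_sizes=bundle.genome.chrom_sizes,
    )
    profs: list[MotifProfile] = []
    rows = []
    for tf, tf_hits in hits.items():
        p = build_profile(tf_hits, dyads, cfg.profile_flank, tf, cl)
        profs.append(p)
        try:
            pcc, pval = occupancy_correlation(p, occ, cfg.occupancy_flank)
        except ValueError:
            pcc, pval = float("nan"), float("nan")
        try:
            r_ed = end_dyad_ratio(p)
        except ValueError:
            r_ed = float("nan")
        rows.append(
            dict(
                tf=tf, cell_line=cl, n_motif_bp=p.n_motif_bp,
                nr_motif_bp=p.nr_motif_bp, occupancy_pcc=pcc, occupancy_p=pval,
                nucleosome_binder=bool(pcc >= 0.2 and pval < 0.05),
                r_end_dyad=r_ed, symmetry_pcc=symmetry_pcc(p),
            )
        )
    summary = pd.DataFrame(rows)
    kept, rejected = clustering_mod.quality_filter(
        profs, cfg.min_nr_bp, cfg.min_sym_pcc
    )
    log.info("profiles: %d built, %d pass QC", len(profs), len(kept))
    result = None
    if len(kept) >= max(cfg.k, 4):
        inputs = [
            clustering_mod.ClusterInput(
                (p.tf_name, p.cell_line),
                clustering_mod.symmetrize(p),
                p.nr_motif_bp,
                symmetry_pcc(p),
            )
            for p in kept
        ]
        result = clustering_mod.cluster_profiles(
            inputs, cfg.k, cfg.seed, cfg.perplexity, cfg.max_sil,
            cfg.use_embedding,
        )
        assign = {k: int(a) for k, a in zip(result.keys, result.assignments)}
        summary["cluster"] = [
            assign.get((tf, cl), pd.NA) for tf in summary["tf"]
        ]
    elif len(profs) and not kept:
        raise ValueError("no clusterable profiles")
    return dict(
        summary=summary, profiles=profs, occupancy=occ, clusters=result,
        rejected=rejected, dyads=dyads, provenance=cfg.manifest(),
    )


def run_all(bundle: Bundle, cfg: RunConfig | None = None) -> dict:
    """Full workflow; reuses the dyad calls and scan hits across stages."""
    cfg = cfg or RunConfig()
    enrich_out = run_enrichment(bundle, cfg)
    prof_out = run_profiles(
        bundle, cfg, dyads=enrich_out["dyads"], hits=enrich_out["hits"]
    )
    return dict(enrichment=enrich_out, profiles=prof_out)


def digest_outputs(out: dict) -> str:
    """Stable digest of the principal tabular outputs (reproducibility check)."""
    import hashlib

    h = hashlib.sha256()
    tab = out["enrichment"]["table"]
    h.update(tab.to_csv(index=False, float_format="%.10g").encode())
    summ = out["profiles"]["summary"]
    h.update(summ.to_csv(index=False, float_format="%.10g").encode())
    return h.hexdigest()
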