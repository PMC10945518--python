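# pioneertf

Pioneer transcription factors (PTFs) are the small subset of TFs that can
recognize their binding motifs on DNA still wrapped around a nucleosome and
trigger local chromatin opening. `pioneertf` is a toolkit for predicting
PTF behavior from standard epigenomic data: it integrates MNase-seq-derived
nucleosome positions, DNase-seq open chromatin, and ChIP-seq binding motifs
to score each TF's propensity to bind nucleosomal DNA, locate *where* on the
nucleosome it binds, and cluster TFs by nucleosome-binding mode. It is aimed
at computational biologists working with ENCODE/Roadmap-style data who want
a transparent, fully scripted version of this analysis, plus a synthetic
data generator that makes every stage testable without downloads.

## The method

**Nucleosome dyads.** Mono-nucleosome MNase-seq fragments of 146–148 bp are
reduced to their midpoints (dyad counts *d(j)*), smoothed with a triweight
kernel

    K(u) = (1 − (u/h)²)³  for |u| ≤ h,  else 0
    D(i) = (1/h) Σⱼ K(i−j) · d(j)        (bandwidth h = 15 bp)

and local maxima of *D* at least 150 bp apart are located. One
representative dyad per maximum is chosen from the raw counts in a 60 bp
window (highest count; ties to the position closest to the maximum).
Nucleosome regions (NRs) are the 147 bp spans dyad ± 73 bp.

**Regions.** Open chromatin = DNase narrow-peak center ± 1000 bp.
Nucleosome-depleted regions (NDRs) = open-chromatin bases not covered by any
120–180 bp mono-nucleosome fragment. Conserved open regions share > 80% of
their bases with another cell line's open set; differentially open regions
overlap it by < 20%.

**The PTF score.** Motifs (JASPAR PFMs, scanned FIMO-style on both strands
at p < 10⁻⁴ with exact DP-computed p-values) are counted base-by-base on NRs
and NDRs, giving a 2×2 table (a, b, c, d), and each TF is scored with the
odds ratio

    Enrichment score = (a/c) / (b/d)

with Fisher's exact test, Benjamini–Hochberg FDR, and an expression filter
(RPKM ≥ 10). Scores > 1 mean the TF's motifs concentrate on nucleosomal
DNA — pioneer-like behavior.

**Binding geometry.** Motif hits are assigned to their closest dyad and
accumulated into per-TF profiles (± 1000 bp). From these we compute the
Pearson correlation with nucleosome occupancy (± 400 bp), the end/dyad
binding ratio R_end/dyad (motif bases at superhelical locations ± 5.5–7
over those at SHL 0–± 1.5), and — after symmetry QC and averaging of the
two nucleosome halves — a t-SNE + k-medoids (k = 6) clustering of binding
modes with silhouette-based outlier removal.

## Worked example

Everything below runs on synthetic data generated by the package itself
(1 Mb genome, 40 TFs of which 10 are planted as pioneers):

```python
from pioneertf import SimulationConfig, simulate_bundle, RunConfig, run_enrichment

bundle = simulate_bundle(SimulationConfig(seed=1))
out = run_enrichment(bundle, RunConfig(mode="all_open"))
print(out["table"][["tf", "a", "c", "score", "q"]].head(3))
print(out["metrics"])
```

prints

```
      tf    a    c     score             q
0  TF009  627  160  4.225267  7.956074e-74
1  TF003  615  192  3.453316  1.630054e-59
2  TF004  600  200  3.234149  6.184632e-54
```

— the top-ranked TFs are planted pioneers: 627 of their motif bases fall on
nucleosome regions versus 160 on nucleosome-depleted regions, an odds ratio
of 4.2 at overwhelming significance — and

```
{'roc_auc': 1.0, 'pr_auc': 1.0, 'max_mcc': 1.0, ...,
 'mw_p': 3.975599023028054e-06}
```

— enrichment scores of the 38 expressed TFs separate the planted pioneer
and canonical labels perfectly (ROC AUC 1.0), and a Mann-Whitney test
rejects equal score distributions at p ≈ 4 × 10⁻⁶. Re-running with
`RunConfig(mode="differential")` (NRs restricted to regions open in cell
line A but closed in B, NDRs to conserved open regions) raises every planted
pioneer's score, e.g. TF009 from 4.2 to 115.

The same workflow is available from the shell:

```bash
pioneertf simulate --out bundle --seed 1
pioneertf run-all --bundle bundle --out-dir results
```

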