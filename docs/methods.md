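# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pioneertf`, and what the synthetic benchmark does and does not show.

## Nucleosome dyad mapping

Dyad positions are fragment midpoints (`start + floor(len/2)`; floor is
symmetric for the dominant 147 bp fragment and the common convention for
even lengths). Only fragments of 146–148 bp enter dyad calling — the
tightest mono-nucleosome size class — while the occupancy and NDR
computations use the looser 120–180 bp class that standard MNase-seq
insert-size filters produce.

Smoothing uses a triweight kernel with bandwidth h = 15 bp. The kernel has
bounded support, so the smoothed track is computed exactly by convolving the
dense count track with the sampled kernel; this is identical to the double
sum over all (i, j) pairs and is asserted against it in the tests to 1e-12.
A small bandwidth trades smoothness for positional accuracy, which is the
right trade for dyad calling.

Local maxima of the smoothed track must be ≥ 150 bp apart. Two choices here
are underdetermined by the mathematical statement and fixed for determinism:
plateau maxima are reported at their lowest coordinate, and the minimum
separation is enforced greedily by descending height (the taller of two
conflicting maxima survives; height ties resolve to the lower coordinate).
Representative dyads are the highest raw count within a 60 bp window around
each maximum, ties broken by distance to the maximum, then lower coordinate.
Because maxima are ≥ 150 bp apart and representatives lie within ± 30 bp of
their maximum, representative dyads are ≥ 90 bp apart by construction.

"Nucleosome occupancy" is operationalized as mean fragment coverage per
dyad-aligned position, the standard MNase-seq estimator; a smoothed
dyad-density alternative is available behind `mode="dyad_density"`. Replicate
fragment sets are pooled after length filtering.

## Region annotation

Open chromatin is the peak center ± 1000 bp (summit column when present,
interval midpoint otherwise), merged. NDRs default to per-base subtraction
of fragment coverage from open regions rather than keeping only entirely
fragment-free open regions: the strict reading would leave almost no NDR
bases in realistic data, while subtraction preserves the intent — genomic
bases free of nucleosomes. Both modes are exposed (`mode="strict"`).

Conserved (> 80% shared) and differential (< 20% overlap) thresholds are
strict inequalities, matching their verbal definitions. Directionality of
the differential comparison is chosen by argument order.

## Motif scanning

PFM counts become log2-odds scores against a background distribution
(uniform by default, for determinism) with pseudocount 0.1:
`log2(((count + pc·bg) / (colsum + pc)) / bg)`.

Scores are quantized to a 1e-3-bit grid. The null distribution of the total
score of a background-random sequence is computed by dynamic-programming
convolution of the per-column score distributions on that grid, and the
scanner evaluates windows with the same quantized integers, so the p-value
attached to a hit is exactly the null tail mass at its score and the p <
1e-4 threshold is self-consistent. At this granularity the rounding
perturbs scores by at most L·5e-4 bits, which keeps p-values near 1e-4
accurate to well under 1% in relative terms. Both strands are scanned; a
minus-strand match is reported on the forward-coordinate interval it
covers. Windows containing N are skipped. Overlapping hits are all
retained; enrichment counting deduplicates per base downstream.

## Enrichment score and testing

The 2×2 table counts genome base pairs, not hits: a = NR bases covered by
≥ 1 motif hit of the TF, c = the same on NDRs, b and d the remaining NR/NDR
bases. Per-base deduplication prevents overlapping hits from inflating a
beyond the NR total. The score is the odds ratio (a/c)/(b/d) = ad/bc; when
any cell is zero the Haldane–Anscombe correction (+0.5 to every cell) is
applied to the score only, keeping scores finite and rankable, while
Fisher's exact test always uses the raw integer table. The test is
two-sided by default (the probability-based definition: summing outcomes at
most as probable as the observed one), since both nucleosome-enriched and
nucleosome-depleted TFs are of interest; one-sided alternatives are
available. The exact test is computed from the hypergeometric pmf per
margin triple, which makes exhaustive sweeps over small tables cheap and is
cross-checked in the tests against both an integer-arithmetic enumeration
and scipy. FDR is Benjamini–Hochberg. Candidates are ranked among expressed
TFs (RPKM ≥ 10) with q below the cut; TFs missing from the expression table
are flagged rather than dropped.

Two analysis modes mirror the two published contrasts: `all_open` (all NRs
versus NDRs in open chromatin) and `differential` (NRs inside differentially
open regions versus NDRs inside conserved open regions). An NR belongs to a
region when its dyad lies inside it.

## Binding profiles and SHL windows

Each hit is assigned to the dyad closest to its midpoint (the unique
strand-invariant per-hit anchor; exact ties go to the lower-coordinate
dyad) and every hit base within ± 1000 bp increments the profile at its
offset. No strand flipping is applied — both strands are counted in genomic
orientation, and the nucleosome's two-fold symmetry is exploited later by
averaging the two halves.

Superhelical locations convert to base pairs at 73/7 ≈ 10.43 bp per SHL
(73 bp from dyad to DNA end over 7 turns), rounding half away from zero;
the ends window (SHL 5.5–7) maps to offsets 57–73 and the dyad window (SHL
0–1.5) to 0–16. R_end/dyad is the ratio of profile mass in the two windows;
a zero dyad window raises an error unless an infinite ratio is explicitly
allowed. The occupancy correlation is a Pearson coefficient over offsets
± 400 bp with a two-sided t-distribution p-value (n − 2 degrees of
freedom); TFs with PCC ≥ 0.2 and p < 0.05 are flagged as
positively-correlated nucleosome binders.

## Clustering

Profiles with fewer than 500 motif bases on NRs, or with a Pearson
correlation below 0.4 between the two nucleosomal halves (offsets ± 1 to
± 73 — the full halves), are removed. Halves are averaged (mean; sum would
be identical after normalization) into a 61-point half-profile covering the
dyad to + 60 bp — the entry/exit DNA is excluded because MNase's AT cutting
bias distorts profile ends — then min-max normalized so shape, not
amplitude, drives clustering. t-SNE (perplexity 30, auto-reduced below
(n−1)/3 for small inputs; fixed seed) projects half-profiles to 2-D, and
PAM k-medoids (deterministic BUILD + best-improvement SWAP on Euclidean
distances, k = 6) clusters the embedding; `use_embedding=False` clusters
the 61-D half-profiles directly as a robustness check. Silhouette widths
are computed once and members with width ≤ 0.25 are relabeled outliers
without recomputation. PAM is a local search: on random instances it can
land a few percent above the exhaustive-optimum cost, which the tests
acknowledge; on separated structures it recovers the planted partition
exactly.

## Dinucleotide QC

Dyad-aligned WW/SS/YY/RR dinucleotide frequencies over offsets −73..+72
(the dinucleotide at offset i spans bases i and i+1, so the last one stays
inside the 147-mer) provide a data-quality readout: rotationally positioned
nucleosomes show ~10 bp periodicity. The periodicity score is the maximum
normalized autocorrelation of the mean-subtracted profile over lags 5–20.

## Synthetic data: what it emulates, and what it does not

The generator plants everything the analysis later estimates. Default
study conditions: one 1 Mb chromosome of uniform-random sequence;
nucleosomes spaced 200 ± 20 bp emitting Poisson(30) fragments each, lengths
147 ± 5 bp, dyad jitter 10 bp; two cell lines; open regions of 2001 bp with
a 1600 bp nucleosome-free core, labeled conserved (open in both lines) or
differential (open in A only) with probability 1/2; 40 TFs (25% pioneers)
with random high-information 8-mers embedded into the genome sequence —
pioneers place 70% of instances on nucleosome regions (inside differential
regions by default, so the differential contrast is testable), canonical
TFs 10%; RPKM is uniform 10–100 with a 10% sub-threshold subset. Half the
genome open is far above physiological values; the choice keeps the NR and
NDR compartments of comparable total size at desk scale so both contingency
margins are well populated and planted pioneers land at odds ratios > 1.
Binding-mode fixtures plant motifs inside stated SHL windows at a 3:1
signal-to-uniform ratio; the dinucleotide fixture plants WW every 10 bp
inside nucleosomes and uses 2 bp dyad jitter, emulating strongly
rotationally positioned nucleosomes so the alignment-sensitive periodicity
readout is informative. Clustering templates are Gaussian bumps at the end,
dyad, and SHL-3 positions plus noise.

Passing these benchmarks shows the machinery is correct and the statistics
behave as designed under the planted model. It does not show performance on
real chromatin: the generator has no MNase sequence bias, no TF co-binding
or motif clustering, no GC structure, no replicate-level batch effects, and
its motif instances are exact consensus sequences. Shuffled-dyad
periodicity power is a noise-floor statistic over only 146 offsets and
fluctuates around 0.1–0.2 across seeds.

## Problem sizes

The standard bundle is 1 Mb / ~2800 nucleosomes / ~85k fragments / 40 TFs ×
100 instances; binding-mode and dinucleotide fixtures use 12 TFs and 300 kb
respectively. These sizes give stable statistics (classification metrics at
these settings are saturated, so seeds move them negligibly) while keeping
the full test suite and the acceptance script in the tens of seconds.
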