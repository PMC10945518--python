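"""Dyad-aligned dinucleotide frequency profiles as a QC of nucleosome calls.

Well-positioned nucleosomes show ~10 bp periodic WW (A/T) and SS (G/C)
dinucleotide patterns along nucleosomal DNA, reflecting rotational
positioning; the strength of that periodicity in dyad-aligned profiles is a
quality check of the dyad calls themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dyads import DyadMap
from .intervals import GenomeModel

DINUC_ALPHABETS = {
    "WW": set("AT"),
    "SS": set("GC"),
    "YY": set("CT"),
    "RR": set("AG"),
}


@dataclass
class DinucProfile:
    dinuc_class: str
    freq: np.ndarray  # offsets -73..+72 (dinucleotide starting at offset)
    n_sequences: int

    def offsets(self) -> np.ndarray:
        return np.arange(-73, 73)


def dinuc_profile(
    dyads: DyadMap, genome: GenomeModel, dinuc_class: str = "WW"
) -> DinucProfile:
    """Fraction of nucleosome regions whose dinucleotide at each dyad-relative
    offset lies in the class alphabet.

    The dinucleotide at offset i spans bases (dyad+i, dyad+i+1); offsets run
    -73..+72 so both bases stay inside the 147-mer.  Regions with N at a
    position are excluded from that offset's denominator.
    """
    if dinuc_class not in DINUC_ALPHABETS:
        raise ValueError(f"unknown dinucleotide class {dinuc_class!r}")
    alphabet = DINUC_ALPHABETS[dinuc_class]
    seqs = genome.require_sequence()
    num = np.zeros(146)
    den = np.zeros(146)
    n_seq = 0
    for chrom, lst in dyads.dyads.items():
        seq = seqs[chrom]
        n = len(seq)
        for pos, _ in lst:
            if pos - 73 < 0 or pos + 74 > n:
                continue
            frag = seq[pos - 73 : pos + 74]
            n_seq += 1
            for i in range(146):
                b1, b2 = frag[i], frag[i + 1]
                if b1 == "N" or b2 == "N":
                    continue
                den[i] += 1
                if b1 in alphabet and b2 in alphabet:
                    num[i] += 1
    with np.errstate(invalid="ignore"):
        freq = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return DinucProfile(dinuc_class, freq, n_seq)


def periodicity_score(p: DinucProfile, lag_min: int = 5, lag_max: int = 20):
    """(best_period, power): the lag in [lag_min, lag_max] maximizing the
    normalized autocorrelation of the mean-subtracted frequency profile."""
    x = np.asarray(p.freq, dtype=float) if not isinstance(p, np.ndarray) else p
    x = x - x.mean()
    denom = float(np.sum(x * x))
    if denom == 0:
        return lag_min, 0.0
    best_lag, best_power = lag_min, -np.inf
    for lag in range(lag_min, lag_max + 1):
        ac = float(np.sum(x[:-lag] * x[lag:])) / denom
        if ac > best_power:
            best_lag, best_power = lag, ac
    return best_lag, best_power
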