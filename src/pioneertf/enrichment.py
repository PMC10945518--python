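"""Motif base-pair enrichment on nucleosome regions versus NDRs.

The pioneer-factor score for one TF is the odds ratio of a 2x2 contingency
table: a = motif-covered bases on nucleosome regions (NRs), b = NR bases
outside motifs, c = motif-covered bases on nucleosome-depleted regions
(NDRs), d = NDR bases outside motifs; score = (a/c)/(b/d).  Significance is
Fisher's exact test on the raw integer table, with Benjamini-Hochberg FDR
across TFs, and candidates are restricted to expressed TFs (RPKM >= 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet
from .motifs import MotifHit, hits_to_intervals


@dataclass
class ContingencyTable:
    a: int  # motif bp on NR
    b: int  # non-motif bp on NR
    c: int  # motif bp on NDR
    d: int  # non-motif bp on NDR

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentRecord:
    tf_name: str
    cell_line: str
    mode: str  # all_open | differential
    table: ContingencyTable
    score: float
    p_value: float
    q_value: float = float("nan")
    expressed: bool | None = None
    rpkm: float = float("nan")


def _covered_bp(hit_union: IntervalSet, regions: IntervalSet) -> int:
    """Bases of ``regions`` covered by the already-merged hit set."""
    from .intervals import _covered_segments

    arrays = hit_union.chrom_arrays()
    total = 0
    for iv in regions:
        if iv.chrom not in arrays:
            continue
        starts, ends = arrays[iv.chrom]
        total += sum(e - s for s, e in _covered_segments(iv.start, iv.end, starts, ends))
    return total


def contingency(
    hits: list[MotifHit] | IntervalSet, nr: IntervalSet, ndr: IntervalSet
) -> ContingencyTable:
    """Per-base-deduplicated motif coverage of NRs and NDRs.

    Overlapping hits are merged first so each genome position counts once.
    """
    if len(nr) == 0 or len(ndr) == 0:
        raise ValueError("empty region set")
    ivs = hits if isinstance(hits, IntervalSet) else hits_to_intervals(hits)
    union = ivs.canonicalize() if len(ivs) else ivs
    nr_bp, ndr_bp = nr.total_bp(), ndr.total_bp()
    a = _covered_bp(union, nr)
    c = _covered_bp(union, ndr)
    return ContingencyTable(a, nr_bp - a, c, ndr_bp - c)


def enrichment_score(t: ContingencyTable) -> float:
    """Odds ratio (a/c)/(b/d); +0.5 to every cell first if any cell is zero
    (Haldane-Anscombe correction), so the score is always finite and > 0."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / c) / (b / d)


def fisher_margin_pvalues(
    n: int, r1: int, cs: int, alternative: str = "two_sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Exact test p-values for every 2x2 table with margins (n, r1, cs).

    n = grand total, r1 = a+b (first row), cs = a+c (first column).  Returns
    (support, pvals) where support holds the admissible values of cell a.
    The hypergeometric pmf over the support is computed once and shared by
    all tables on that margin, which makes exhaustive sweeps cheap.
    """
    if n == 0:
        return np.array([0]), np.array([1.0])
    lo, hi = max(0, cs - (n - r1)), min(r1, cs)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, cs, r1)
    if alternative == "two_sided":
        # sum of outcomes no more probable than the observed one
        order = np.argsort(pmf, kind="stable")
        cum = np.cumsum(pmf[order])
        idx = np.searchsorted(pmf[order], pmf * (1 + 1e-7), side="right") - 1
        pvals = cum[idx]
    elif alternative == "greater":
        pvals = np.cumsum(pmf[::-1])[::-1]
    elif alternative == "less":
        pvals = np.cumsum(pmf)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return support, np.minimum(pvals, 1.0)


def fisher_p(t: ContingencyTable, alternative: str = "two_sided") -> float:
    """Exact hypergeometric p-value for the 2x2 table (raw integer cells).

    ``two_sided`` sums the probabilities of all tables (with the observed
    margins) at most as probable as the observed one; ``greater`` tests
    enrichment of cell a.
    """
    n = t.a + t.b + t.c + t.d
    if n == 0:
        return 1.0
    support, pvals = fisher_margin_pvalues(n, t.a + t.b, t.a + t.c, alternative)
    return float(pvals[t.a - support[0]])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)*n/j,
    clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def score_tf(
    tf_name: str,
    cell_line: str,
    hits: list[MotifHit] | IntervalSet,
    nr: IntervalSet,
    ndr: IntervalSet,
    mode: str = "all_open",
    alternative: str = "two_sided",
) -> EnrichmentRecord:
    t = contingency(hits, nr, ndr)
    return EnrichmentRecord(
        tf_name, cell_line, mode, t, enrichment_score(t), fisher_p(t, alternative)
    )


def attach_fdr(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """BH q-values across one batch of records (in place; returned for chaining)."""
    q = bh_fdr([r.p_value for r in records])
    for r, qv in zip(records, q):
        r.q_value = float(qv)
    return records


def rank_candidates(
    records: list[EnrichmentRecord],
    rpkm: pd.DataFrame,
    rpkm_min: float = 10.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Expressed (RPKM >= rpkm_min), significant (q < q_max) TFs ranked by
    descending enrichment score.

    ``rpkm`` has columns tf, cell_line, rpkm.  TFs absent from the table are
    flagged (``expressed`` = NA, ``rank`` = NA) rather than silently dropped;
    non-expressed and non-significant records are kept with ``rank`` = NA.
    """
    lookup = {
        (row.tf, row.cell_line): float(row.rpkm) for row in rpkm.itertuples()
    }
    rows = []
    for r in records:
        key = (r.tf_name, r.cell_line)
        rp = lookup.get(key)
        expressed = None if rp is None else rp >= rpkm_min
        rows.append(
            dict(
                tf=r.tf_name,
                cell_line=r.cell_line,
                mode=r.mode,
                a=r.table.a,
                b=r.table.b,
                c=r.table.c,
                d=r.table.d,
                score=r.score,
                p=r.p_value,
                q=r.q_value,
                rpkm=np.nan if rp is None else rp,
                expressed=expressed,
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["rank"] = pd.Series(dtype="Int64")
        return df
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    ranks = pd.Series(pd.NA, index=df.index, dtype="Int64")
    # ranks assigned in score order among eligible rows only
    r = 1
    for i in df.index:
        if df.loc[i, "expressed"] == True and df.loc[i, "q"] < q_max:  # noqa: E712
            ranks[i] = r
            r += 1
        else:
            ranks[i] = pd.NA
    df["rank"] = ranks
    return df
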