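"""JASPAR parsing, PWM construction, exact p-values, and two-strand scanning."""

import itertools

import numpy as np
import pytest

from pioneertf.intervals import GenomeModel, GenomicInterval, IntervalSet
from pioneertf.motifs import (
    BASES,
    GRANULARITY,
    PFM,
    build_pwm,
    encode_sequence,
    parse_jaspar,
    scan,
    score_pvalues,
    write_jaspar,
)

JASPAR_TEXT = """>MA0001 TFA
A  [ 10  0  5  5 ]
C  [  0 10  5  0 ]
G  [  0  0  0  5 ]
T  [  0  0  0  0 ]
>MA0002 TFB
A  [ 1 1 ]
C  [ 1 1 ]
G  [ 1 1 ]
T  [ 1 1 ]
"""


class TestJaspar:
    def test_parse_two_records(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        pfms = parse_jaspar(p)
        assert [m.tf_name for m in pfms] == ["TFA", "TFB"]
        assert pfms[0].length == 4 and pfms[1].length == 2
        assert pfms[0].matrix[0, 0] == 10

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.jaspar"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_jaspar(p)

    def test_write_read_round_trip(self, tmp_path):
        pfm = PFM("ROUND", np.array([[9, 1], [0, 3], [1, 0], [0, 6]], dtype=float))
        p = tmp_path / "rt.jaspar"
        write_jaspar([pfm], p)
        back = parse_jaspar(p)[0]
        assert back.tf_name == "ROUND"
        assert np.array_equal(back.matrix, pfm.matrix)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            PFM("BAD", np.zeros((3, 5)))
        with pytest.raises(ValueError):
            PFM("BAD", np.zeros((4, 5)))  # zero column sums


class TestBuildPwm:
    def test_pure_column_is_two_bits(self):
        pfm = PFM("X", np.array([[100], [0], [0], [0]], dtype=float))
        pwm = build_pwm(pfm, pseudocount=0.0)
        assert pwm.matrix[0, 0] == pytest.approx(2.0)

    def test_uniform_counts_zero_bits(self):
        pfm = PFM("X", np.full((4, 3), 25.0))
        pwm = build_pwm(pfm, pseudocount=0.0)
        assert np.allclose(pwm.matrix, 0.0)

    def test_pseudocount_keeps_scores_finite(self):
        pfm = PFM("X", np.array([[100], [0], [0], [0]], dtype=float))
        pwm = build_pwm(pfm, pseudocount=0.1)
        assert np.all(np.isfinite(pwm.matrix))

    def test_zero_background_rejected(self):
        pfm = PFM("X", np.ones((4, 2)))
        with pytest.raises(ValueError):
            build_pwm(pfm, background=np.array([0.5, 0.5, 0.0, 0.0]))


def enumerate_pvalues(pwm, scores_of_interest):
    """Oracle: exhaustive scan of all 4^L background sequences using the same
    quantized per-column scores as the scanner."""
    im = pwm.int_matrix
    L = pwm.length
    bg = pwm.background
    out = {}
    totals = np.zeros(4**L, dtype=np.int64)
    probs = np.ones(4**L)
    for i, word in enumerate(itertools.product(range(4), repeat=L)):
        totals[i] = sum(im[b, j] for j, b in enumerate(word))
        probs[i] = np.prod([bg[b] for b in word])
    for s in scores_of_interest:
        out[s] = probs[totals >= s].sum()
    return out


class TestScorePvalues:
    def test_consensus_pvalue_is_quarter_to_the_L(self, rng):
        pfm = PFM("X", np.eye(4)[rng.integers(0, 4, 8)].T * 100)
        pwm = build_pwm(pfm)
        dist = score_pvalues(pwm)
        max_score = int(pwm.int_matrix.max(axis=0).sum())
        assert dist.pvalue_int(max_score) == pytest.approx(0.25**8, rel=1e-9)

    def test_minus_infinity_covers_everything(self):
        pfm = PFM("X", np.full((4, 4), 5.0))
        dist = score_pvalues(build_pwm(pfm))
        assert dist.pvalue(-1e9) == pytest.approx(1.0)

    def test_survival_non_increasing(self, rng):
        pfm = PFM("X", rng.integers(1, 50, (4, 6)).astype(float))
        dist = score_pvalues(build_pwm(pfm))
        assert np.all(np.diff(dist.survival) <= 0)

    @pytest.mark.parametrize("L", [3, 5, 8])
    def test_matches_exhaustive_enumeration(self, rng, L):
        for _ in range(3):
            pfm = PFM("X", rng.integers(0, 60, (4, L)).astype(float) + rng.integers(1, 3, (4, L)))
            pwm = build_pwm(pfm)
            dist = score_pvalues(pwm)
            probe = [int(s) for s in rng.choice(dist.support, 5)]
            oracle = enumerate_pvalues(pwm, probe)
            for s in probe:
                assert dist.pvalue_int(s) == pytest.approx(oracle[s], abs=1e-9)


def _genome_with(seq: str) -> GenomeModel:
    return GenomeModel({"chr1": len(seq)}, {"chr1": seq})


CONSENSUS = "ACGTACGT"
RC = "ACGTACGT"[::-1].translate(str.maketrans("ACGT", "TGCA"))


def _consensus_pfm() -> PFM:
    mat = np.full((4, 8), 0.0)
    for j, b in enumerate(CONSENSUS):
        mat[BASES.index(b), j] = 100
    return PFM("CONS", mat)


class TestScan:
    def test_consensus_found_on_plus_strand(self, rng):
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        seq = bg[:12] + CONSENSUS + bg[20:]
        genome = _genome_with(seq)
        peaks = IntervalSet("p", [GenomicInterval("chr1", 0, 200)])
        hits = scan(build_pwm(_consensus_pfm()), peaks, genome, 1e-4)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.interval.start == 12 and h.interval.end == 20 for h in plus)
        top = max(hits, key=lambda h: h.score)
        assert top.p_value < 1e-4

    def test_reverse_complement_same_interval_minus_strand(self, rng):
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        seq = bg[:12] + RC + bg[20:]
        genome = _genome_with(seq)
        peaks = IntervalSet("p", [GenomicInterval("chr1", 0, 200)])
        hits = scan(build_pwm(_consensus_pfm()), peaks, genome, 1e-4)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.interval.start == 12 and h.interval.end == 20 for h in minus)

    def test_mirror_symmetry_of_hit_sets(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        seq = seq[:50] + CONSENSUS + seq[58:]
        rc_seq = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        pwm = build_pwm(_consensus_pfm())
        peaks = IntervalSet("p", [GenomicInterval("chr1", 0, 300)])
        h1 = scan(pwm, peaks, _genome_with(seq), 1e-3)
        h2 = scan(pwm, peaks, _genome_with(rc_seq), 1e-3)
        m1 = sorted((h.interval.start, h.strand) for h in h1)
        m2 = sorted((300 - h.interval.end, {"+": "-", "-": "+"}[h.strand]) for h in h2)
        assert m1 == m2

    def test_hit_count_monotone_in_threshold(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        pwm = build_pwm(PFM("X", rng.integers(1, 30, (4, 6)).astype(float)))
        peaks = IntervalSet("p", [GenomicInterval("chr1", 0, 500)])
        counts = [len(scan(pwm, peaks, _genome_with(seq), p)) for p in (1e-4, 1e-3, 1e-2)]
        assert counts == sorted(counts)

    def test_windows_with_n_skipped(self):
        seq = "ACGTACGTNNNNACGTACGT"
        hits = scan(
            build_pwm(_consensus_pfm()),
            IntervalSet("p", [GenomicInterval("chr1", 0, len(seq))]),
            _genome_with(seq),
            1e-3,
        )
        assert all("N" not in seq[h.interval.start : h.interval.end] for h in hits)

    def test_encode_sequence(self):
        assert list(encode_sequence("ACGTN")) == [0, 1, 2, 3, -1]
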