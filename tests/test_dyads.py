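"""Dyad counting, kernel smoothing, local maxima, and representative dyads."""

import numpy as np
import pytest

from pioneertf.dyads import (
    DyadCounts,
    DyadMap,
    count_dyads,
    find_local_maxima,
    nucleosome_regions,
    occupancy_profile,
    select_representative_dyads,
    smooth_counts,
    triweight_kernel,
)
from pioneertf.intervals import GenomeModel, GenomicInterval, IntervalSet


def frags(*spans):
    return IntervalSet("f", [GenomicInterval("chr1", s, e) for s, e in spans])


SIZES = {"chr1": 100_000}


class TestCountDyads:
    def test_midpoint_of_147mer(self):
        out = count_dyads(frags((100, 247)), SIZES)
        assert out["chr1"].counts == {173: 1}

    def test_length_filter_excludes_150(self):
        out = count_dyads(frags((100, 250)), SIZES)
        assert out == {}

    def test_counts_add(self):
        out = count_dyads(frags((100, 247), (100, 247)), SIZES)
        assert out["chr1"].counts == {173: 2}

    def test_even_length_floor_midpoint(self):
        out = count_dyads(frags((100, 246)), SIZES)
        assert out["chr1"].counts == {173: 1}


class TestSmoothing:
    def test_single_count_kernel_values(self):
        s = smooth_counts(DyadCounts("chr1", {1000: 4}, 2000), h=15)
        assert s.D[1000] == pytest.approx(4 / 15, abs=1e-12)
        assert s.D[1007] == pytest.approx(4 * (1 - (7 / 15) ** 2) ** 3 / 15, abs=1e-12)
        assert s.D[1015] == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        h = 15
        for _ in range(20):
            pos = rng.choice(3000, size=rng.integers(1, 40), replace=False)
            counts = {int(p): int(rng.integers(1, 6)) for p in pos}
            s = smooth_counts(DyadCounts("chr1", counts, 3000), h)
            brute = np.zeros(3000)
            for i in range(3000):
                brute[i] = sum(
                    c * float(triweight_kernel(np.array([i - j]), h)[0])
                    for j, c in counts.items()
                ) / h
            assert np.max(np.abs(s.D - brute)) < 1e-12

    def test_total_mass_scales_with_counts(self, rng):
        h = 15
        counts = {int(p): int(c) for p, c in zip(rng.choice(2000, 10, replace=False) + 500, rng.integers(1, 9, 10))}
        s = smooth_counts(DyadCounts("chr1", counts, 4000), h)
        kernel_mass = float(triweight_kernel(np.arange(-h, h + 1), h).sum()) / h
        assert s.D.sum() == pytest.approx(sum(counts.values()) * kernel_mass, rel=1e-10)

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError):
            smooth_counts(DyadCounts("chr1", {5: 1}, 10), h=0)


def brute_force_maxima(D, min_sep):
    """Oracle: plateau-aware local maxima, then greedy keep-highest."""
    cands = []
    i = 0
    n = len(D)
    while i < n:
        if D[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and D[j + 1] == D[i]:
            j += 1
        left = D[i - 1] if i > 0 else 0
        right = D[j + 1] if j + 1 < n else 0
        if D[i] > left and D[i] > right:
            cands.append(i)
        i = j + 1
    kept = []
    for p in sorted(cands, key=lambda q: (-D[q], q)):
        if all(abs(p - k) >= min_sep for k in kept):
            kept.append(p)
    return sorted(kept)


class TestLocalMaxima:
    def _smoothed(self, counts, n=2000):
        return smooth_counts(DyadCounts("chr1", counts, n), h=15)

    def test_single_bump(self):
        s = self._smoothed({500: 3})
        assert find_local_maxima(s, 150) == [500]

    def test_close_bumps_keep_higher(self):
        s = self._smoothed({500: 3, 600: 5})
        assert find_local_maxima(s, 150) == [600]

    def test_far_bumps_both_kept(self):
        s = self._smoothed({500: 3, 700: 5})
        assert find_local_maxima(s, 150) == [500, 700]

    def test_plateau_lowest_coordinate(self):
        # two equal counts 2h apart create a flat saddle; each is a max
        D = np.zeros(1000)
        D[500:505] = 2.0  # synthetic plateau
        D[400] = 1.0
        from pioneertf.dyads import SmoothedCounts

        out = find_local_maxima(SmoothedCounts("chr1", D, 15), min_sep=50)
        assert 500 in out and not any(p in out for p in range(501, 505))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            pos = rng.choice(1500, size=rng.integers(1, 15), replace=False) + 100
            counts = {int(p): int(rng.integers(1, 5)) for p in pos}
            s = self._smoothed(counts)
            assert find_local_maxima(s, 150) == brute_force_maxima(s.D, 150)

    def test_all_zero_empty(self):
        s = self._smoothed({})
        assert find_local_maxima(s, 150) == []


class TestRepresentativeDyads:
    def _select(self, counts, maxima, window=60):
        raw = {"chr1": DyadCounts("chr1", counts, 10_000)}
        return select_representative_dyads(raw, {"chr1": maxima}, window)

    def test_highest_count_wins(self):
        out = self._select({990: 5, 1010: 3}, [1000])
        assert out.dyads["chr1"] == [(990, 5)]

    def test_tie_breaks_to_closest(self):
        out = self._select({995: 4, 1003: 4}, [1000])
        assert out.dyads["chr1"] == [(1003, 4)]

    def test_equal_distance_lower_coordinate(self):
        out = self._select({997: 4, 1003: 4}, [1000])
        assert out.dyads["chr1"] == [(997, 4)]

    def test_empty_window_no_representative(self):
        out = self._select({2000: 5}, [1000])
        assert out.dyads.get("chr1", []) == []

    def test_representatives_at_least_90bp_apart(self, default_dyads):
        for chrom, lst in default_dyads.dyads.items():
            pos = np.array([p for p, _ in lst])
            assert np.all(np.diff(pos) >= 90)


class TestNucleosomeRegions:
    genome = GenomeModel({"chr1": 100_000})

    def test_147bp_window(self):
        dm = DyadMap({"chr1": [(1000, 3)]})
        out = nucleosome_regions(dm, self.genome)
        assert [(i.start, i.end) for i in out] == [(927, 1074)]

    def test_boundary_clip(self):
        dm = DyadMap({"chr1": [(10, 1)]})
        out = nucleosome_regions(dm, self.genome)
        assert [(i.start, i.end) for i in out] == [(0, 84)]

    def test_empty_map(self):
        assert len(nucleosome_regions(DyadMap({}), self.genome)) == 0


class TestOccupancy:
    def test_single_fragment_coverage(self):
        dm = DyadMap({"chr1": [(1000, 1)]})
        occ = occupancy_profile(frags((927, 1074)), dm, flank=400, chrom_sizes=SIZES)
        offs = np.arange(-400, 401)
        assert np.all(occ[(offs >= -73) & (offs <= 73)] == 1.0)
        assert np.all(occ[np.abs(offs) > 73] == 0.0)

    def test_no_fragments_zero(self):
        dm = DyadMap({"chr1": [(1000, 1)]})
        occ = occupancy_profile(IntervalSet("f"), dm, flank=400, chrom_sizes=SIZES)
        assert np.all(occ == 0.0)

    def test_mean_over_dyads(self):
        dm = DyadMap({"chr1": [(1000, 1), (5000, 1)]})
        occ = occupancy_profile(frags((927, 1074)), dm, flank=400, chrom_sizes=SIZES)
        assert occ[400] == 0.5  # offset 0 covered at one of two dyads

    def test_empty_dyads_error(self):
        with pytest.raises(ValueError, match="no dyads"):
            occupancy_profile(frags((0, 147)), DyadMap({}), 400)

    def test_length_filter_applies(self):
        dm = DyadMap({"chr1": [(1000, 1)]})
        occ = occupancy_profile(frags((950, 1050)), dm, flank=100, chrom_sizes=SIZES)
        assert np.all(occ == 0.0)  # 100 bp fragment outside 120-180
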