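"""Profile QC filtering, symmetrization, k-medoids, and outlier removal."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pioneertf.clustering import (
    OUTLIER,
    ClusterInput,
    ClusterResult,
    cluster_profiles,
    embed_2d,
    kmedoids,
    quality_filter,
    remove_outliers,
    symmetrize,
)
from pioneertf.profiles import MotifProfile
from pioneertf.simulate import template_half_profiles


def _profile(counts, tf="T"):
    return MotifProfile(tf, "A", np.asarray(counts, dtype=np.int64), 1000)


def _symmetric_profile(rng, nr_bp=1000):
    counts = np.zeros(2001, dtype=np.int64)
    shape = rng.integers(1, 30, 74)
    counts[1000 : 1074] = shape
    counts[927 : 1001] = shape[::-1]
    p = _profile(counts)
    p.nr_motif_bp = nr_bp
    return p


class TestSymmetrize:
    def test_symmetric_fixed_point(self, rng):
        p = _symmetric_profile(rng)
        half = symmetrize(p)
        ref = p.counts[1000:1061].astype(float)
        ref = (ref - ref.min()) / (ref.max() - ref.min())
        assert np.allclose(half, ref)

    def test_averaging_rule(self):
        counts = np.zeros(2001, dtype=np.int64)
        counts[1000 + 10] = 4
        counts[1000 - 10] = 2
        half_raw = (counts[1010] + counts[990]) / 2
        half = symmetrize(_profile(counts))
        assert half[10] == 1.0 and half_raw == 3  # only nonzero -> max after scaling

    def test_entry_exit_excluded(self):
        a = np.zeros(2001, dtype=np.int64)
        a[1000 + 30] = 7
        b = a.copy()
        b[1000 + 70] = 99  # beyond offset 60: must not matter
        assert np.allclose(symmetrize(_profile(a)), symmetrize(_profile(b)))


class TestQualityFilter:
    def test_low_nr_mass_rejected(self, rng):
        p = _symmetric_profile(rng, nr_bp=499)
        kept, rej = quality_filter([p])
        assert kept == [] and rej[0][1] == "nr_bp"

    def test_symmetric_enough_kept(self, rng):
        p = _symmetric_profile(rng, nr_bp=10_000)
        kept, rej = quality_filter([p])
        assert len(kept) == 1 and rej == []

    def test_asymmetric_rejected(self, rng):
        counts = np.zeros(2001, dtype=np.int64)
        counts[1001:1074] = rng.integers(1, 20, 73)
        counts[927:1000] = rng.integers(1, 20, 73)  # independent halves
        p = _profile(counts)
        p.nr_motif_bp = 10_000
        kept, rej = quality_filter([p], min_sym_pcc=0.99)
        assert kept == [] and rej[0][1] == "symmetry"


def brute_force_kmedoids(points, k):
    """Oracle: best medoid set by exhaustive search (tiny n only)."""
    n = len(points)
    dist = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    best, best_cost = None, np.inf
    for combo in itertools.combinations(range(n), k):
        cost = dist[:, list(combo)].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = combo, cost
    return best, best_cost


class TestKmedoids:
    def test_two_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 0.3, (6, 2))
        b = rng.normal(10, 0.3, (6, 2))
        pts = np.vstack([a, b])
        assign, med = kmedoids(pts, 2, seed=0)
        assert len(set(assign[:6])) == 1 and len(set(assign[6:])) == 1
        assert assign[0] != assign[6]

    def test_near_optimal_cost_vs_brute_force(self, rng):
        # PAM is a local search; build+swap should land within a few percent
        # of the exhaustive optimum on small random instances
        for _ in range(5):
            pts = rng.uniform(0, 10, (10, 2))
            assign, med = kmedoids(pts, 3, seed=0)
            dist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            cost = dist[:, med].min(axis=1).sum()
            _, best_cost = brute_force_kmedoids(pts, 3)
            assert best_cost - 1e-9 <= cost <= best_cost * 1.10

    def test_separated_blobs_match_brute_force_assignment(self, rng):
        a = rng.normal(0, 0.4, (6, 2))
        b = rng.normal(8, 0.4, (6, 2))
        pts = np.vstack([a, b])
        assign, med = kmedoids(pts, 2, seed=0)
        best_med, _ = brute_force_kmedoids(pts, 2)
        dist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        brute_assign = np.argmin(dist[:, list(best_med)], axis=1)
        same = np.mean(assign == brute_assign)
        assert same in (0.0, 1.0)  # identical partition up to label swap

    def test_k_one_minimizes_total_distance(self, rng):
        pts = rng.uniform(0, 5, (8, 2))
        assign, med = kmedoids(pts, 1, seed=0)
        dist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        assert med[0] == np.argmin(dist.sum(axis=1))
        assert np.all(assign == 0)

    def test_k_equals_n_zero_cost(self, rng):
        pts = rng.uniform(0, 5, (5, 2))
        assign, med = kmedoids(pts, 5, seed=0)
        assert sorted(med) == list(range(5))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kmedoids(np.zeros((3, 2)), 4)


class TestEmbedding:
    def test_shape_and_determinism(self, rng):
        X, _ = template_half_profiles(20, seed=5)
        inputs = [ClusterInput(("t%d" % i, "A"), X[i]) for i in range(20)]
        e1 = embed_2d(inputs, seed=7)
        e2 = embed_2d(inputs, seed=7)
        assert e1.shape == (20, 2)
        assert np.array_equal(e1, e2)

    def test_duplicates_stay_close(self):
        X, _ = template_half_profiles(30, seed=3)
        X[1] = X[0]
        inputs = [ClusterInput(("t%d" % i, "A"), X[i]) for i in range(30)]
        emb = embed_2d(inputs, seed=1)
        d01 = np.linalg.norm(emb[0] - emb[1])
        from scipy.spatial.distance import pdist

        assert d01 < np.median(pdist(emb))

    def test_too_few_inputs(self):
        with pytest.raises(ValueError):
            embed_2d([ClusterInput(("a", "A"), np.zeros(61))] * 3)


def brute_silhouette(points, labels, i):
    d = np.sqrt(((points - points[i]) ** 2).sum(-1))
    own = labels[i]
    a = d[(labels == own) & (np.arange(len(points)) != i)].mean()
    b = min(d[labels == c].mean() for c in set(labels) if c != own)
    return (b - a) / max(a, b)


class TestOutliers:
    def _result(self, rng):
        a = rng.normal(0, 0.2, (8, 2))
        b = rng.normal(6, 0.2, (8, 2))
        mid = np.array([[3.0, 3.0]])  # equidistant -> silhouette near 0
        pts = np.vstack([a, b, mid])
        from sklearn.metrics import silhouette_samples

        assign, med = kmedoids(pts, 2, seed=0)
        sil = silhouette_samples(pts, assign)
        return pts, ClusterResult(
            [("t%d" % i, "A") for i in range(17)], assign, med, sil
        )

    def test_equidistant_point_flagged(self, rng):
        pts, res = self._result(rng)
        out = remove_outliers(res, 0.25)
        assert out.assignments[-1] == OUTLIER
        assert np.all(out.assignments[:16] != OUTLIER)

    def test_silhouettes_match_brute_force(self, rng):
        pts, res = self._result(rng)
        for i in range(len(pts)):
            assert res.silhouettes[i] == pytest.approx(
                brute_silhouette(pts, res.assignments, i), abs=1e-9
            )

    def test_low_threshold_removes_nothing(self, rng):
        pts, res = self._result(rng)
        out = remove_outliers(res, -1.0)
        assert np.all(out.assignments != OUTLIER)

    def test_single_cluster_rejected(self):
        res = ClusterResult(
            [("a", "A"), ("b", "A")], np.zeros(2, dtype=int), np.array([0]),
            np.zeros(2),
        )
        with pytest.raises(ValueError, match="silhouette"):
            remove_outliers(res)


class TestPlantedStructure:
    def test_three_templates_recovered_across_seeds(self):
        """End-, dyad-, and mid-SHL-binder templates separate cleanly."""
        for seed in range(10):
            X, labels = template_half_profiles(60, seed=seed)
            inputs = [ClusterInput(("t%d" % i, "A"), X[i]) for i in range(60)]
            res = cluster_profiles(inputs, k=3, seed=seed, max_sil=-1.0)
            ari = adjusted_rand_score(labels, res.assignments)
            assert ari >= 0.9

    def test_pipeline_reproducibility(self):
        X, _ = template_half_profiles(30, seed=2)
        inputs = [ClusterInput(("t%d" % i, "A"), X[i]) for i in range(30)]
        r1 = cluster_profiles(inputs, k=3, seed=9)
        r2 = cluster_profiles(inputs, k=3, seed=9)
        assert np.array_equal(r1.assignments, r2.assignments)
        assert np.array_equal(r1.silhouettes, r2.silhouettes)
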