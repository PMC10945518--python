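"""Quality filtering, symmetrization, t-SNE embedding, and PAM k-medoids
clustering of TF binding-motif profiles.

Profiles with under 500 motif bases on nucleosome regions or with
half-profile symmetry PCC below 0.4 are dropped; the two nucleosomal halves
are averaged into a 61-point half-profile (dyad to +60 bp, excluding the
MNase-biased entry/exit DNA), min-max normalized, embedded in 2-D with
t-SNE, and clustered with PAM k-medoids (k = 6).  Members with silhouette
width <= 0.25 are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .profiles import MotifProfile, symmetry_pcc

OUTLIER = -1


@dataclass
class ClusterInput:
    key: tuple[str, str]  # (tf_name, cell_line)
    half_profile: np.ndarray  # offsets 0..60, normalized to [0, 1]
    nr_motif_bp: int = 0
    symmetry_pcc: float = float("nan")


@dataclass
class ClusterResult:
    keys: list[tuple[str, str]]
    assignments: np.ndarray  # cluster id per key, OUTLIER (-1) for outliers
    medoid_indices: np.ndarray
    silhouettes: np.ndarray
    embedding: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def symmetrize(p: MotifProfile, half: int = 60) -> np.ndarray:
    """Average the two nucleosomal halves into offsets 0..half, then min-max
    normalize.  half[i] = (X(+i) + X(-i))/2, half[0] = X(0)."""
    c = p.counts.astype(float)
    f = p.flank
    out = np.empty(half + 1)
    out[0] = c[f]
    for i in range(1, half + 1):
        out[i] = (c[f + i] + c[f - i]) / 2.0
    lo, hi = out.min(), out.max()
    return np.zeros_like(out) if hi == lo else (out - lo) / (hi - lo)


def quality_filter(
    profiles: list[MotifProfile],
    min_nr_bp: int = 500,
    min_sym_pcc: float = 0.4,
) -> tuple[list[MotifProfile], list[tuple[tuple[str, str], str]]]:
    """Drop under-represented (< min_nr_bp motif bases on NRs) and asymmetric
    (half-profile PCC < min_sym_pcc) profiles.  Returns (kept, rejections);
    each rejection records the key and the first failed criterion."""
    kept, rejected = [], []
    for p in profiles:
        key = (p.tf_name, p.cell_line)
        if p.nr_motif_bp < min_nr_bp:
            rejected.append((key, "nr_bp"))
            continue
        pcc = symmetry_pcc(p)
        if not (pcc >= min_sym_pcc):  # NaN also fails
            rejected.append((key, "symmetry"))
            continue
        kept.append(p)
    return kept, rejected


def embed_2d(
    inputs: list[ClusterInput], seed: int = 1234, perplexity: float = 30.0
) -> np.ndarray:
    """t-SNE projection of the half-profiles onto two dimensions.

    Perplexity is auto-reduced below (n-1)/3 for small inputs; fixed seed
    gives reproducible coordinates.
    """
    n = len(inputs)
    if n < 4:
        raise ValueError("need at least 4 profiles to embed")
    X = np.vstack([ci.half_profile for ci in inputs])
    perp = min(perplexity, max(2.0, (n - 1) / 3.0))
    ts = TSNE(
        n_components=2,
        perplexity=perp,
        random_state=seed,
        init="pca",
        max_iter=1000,
    )
    return ts.fit_transform(X).astype(float)


def kmedoids(points: np.ndarray, k: int, seed: int = 1234, max_iter: int = 300):
    """PAM k-medoids (BUILD + SWAP) on Euclidean distances.

    Deterministic: BUILD greedily picks the medoid set minimizing total
    distance; SWAP applies the best improving (medoid, non-medoid) exchange
    until none improves.  Returns (assignments, medoid_indices).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k > n:
        raise ValueError("k > number of points")
    if k < 1:
        raise ValueError("k must be >= 1")
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP
    for _ in range(max_iter):
        cur_cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1 :]
            for h in range(n):
                if h in medoids:
                    continue
                cand = others + [h]
                cost = dist[:, cand].min(axis=1).sum()
                delta = cost - cur_cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    medoid_arr = np.array(medoids)
    assignments = np.argmin(dist[:, medoid_arr], axis=1)
    return assignments, medoid_arr


def cluster_profiles(
    inputs: list[ClusterInput],
    k: int = 6,
    seed: int = 1234,
    perplexity: float = 30.0,
    max_sil: float = 0.25,
    use_embedding: bool = True,
) -> ClusterResult:
    """Embed (optionally), cluster with PAM, and flag silhouette outliers."""
    X = np.vstack([ci.half_profile for ci in inputs])
    emb = embed_2d(inputs, seed, perplexity) if use_embedding else None
    pts = emb if use_embedding else X
    assignments, medoid_idx = kmedoids(pts, k, seed)
    res = ClusterResult(
        keys=[ci.key for ci in inputs],
        assignments=assignments,
        medoid_indices=medoid_idx,
        silhouettes=np.full(len(inputs), np.nan),
        embedding=emb,
        provenance=dict(
            k=k, seed=seed, perplexity=perplexity, max_sil=max_sil,
            use_embedding=use_embedding,
        ),
    )
    if k >= 2:
        res.silhouettes = silhouette_samples(pts, assignments)
        res = remove_outliers(res, max_sil)
    return res


def remove_outliers(result: ClusterResult, max_sil: float = 0.25) -> ClusterResult:
    """Relabel members with silhouette width <= max_sil as outliers.

    Silhouettes are computed once, before removal, and are not revised."""
    labels = result.assignments
    if len(np.unique(labels[labels != OUTLIER])) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    new = labels.copy()
    new[result.silhouettes <= max_sil] = OUTLIER
    return ClusterResult(
        result.keys,
        new,
        result.medoid_indices,
        result.silhouettes,
        result.embedding,
        result.provenance,
    )
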