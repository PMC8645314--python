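"""Two-step temporal cluster analysis of face dissimilarities.

The pipeline mirrors the standard exploratory recipe for recovering episodes
of life from pairwise dissimilarity data:

1. embed the dissimilarity matrix into a low-dimensional *face space* with
   classical (Torgerson) multidimensional scaling,
2. select the number of clusters k by the gap statistic, cross-checked
   against the elbow criterion on the within-groups sum of squares,
3. cut a Ward dendrogram at k and refine the partition with k-means seeded
   at the Ward cluster means (Milligan's two-step routine),
4. flag far-isolated singleton clusters as outliers.

All distances are Euclidean.  The whole routine is deterministic given the
input and a seed (k-means uses the Ward means as its only initialisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "ClusterSolution",
    "GapResult",
    "mds_embed",
    "ward_cluster",
    "elbow_profile",
    "gap_statistic",
    "two_step",
    "flag_outliers",
]


@dataclass
class ClusterSolution:
    """A flat partition plus its within-groups sum of squares."""

    k: int
    labels: np.ndarray
    within_ss: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0 or (self.labels.size and self.labels.max() >= self.k):
            raise ValueError("labels must lie in [0, k)")

    def to_dict(self, ids: list[str] | None = None) -> dict:
        ids = ids or [str(i) for i in range(len(self.labels))]
        return {
            "k": self.k,
            "within_ss": self.within_ss,
            "method": self.method,
            "labels": {i: int(l) for i, l in zip(ids, self.labels)},
            "diagnostics": self.diagnostics,
        }


@dataclass
class GapResult:
    """Gap-statistic profile and the chosen number of clusters.

    chosen_k is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}; the
    standard errors s_k carry the sqrt(1 + 1/B) simulation correction.
    """

    ks: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    B: int
    chosen_k: int

    def table(self):
        import pandas as pd

        return pd.DataFrame({"k": self.ks, "gap": self.gap, "s": self.s})


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("D must have a zero diagonal")
    return D


def mds_embed(D: np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a dissimilarity matrix.

    Double-centers -D^2/2 and keeps the top ``dim`` spectral components.
    Exact (up to rigid motion) when D is Euclidean of intrinsic dimension
    <= dim; otherwise the discarded eigenvalues are the residual stress.
    Negative eigenvalues (non-Euclidean input) contribute zero coordinates.
    """
    D = _check_dissimilarity(D)
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:dim]
    vals = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(vals)
    return coords


def _within_ss_from_D(D: np.ndarray, labels: np.ndarray) -> float:
    """Within-groups SS from distances alone: W = sum_c sum_{i<j in c} d_ij^2 / n_c."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        w += (sub ** 2).sum() / (2.0 * len(idx))
    return float(w)


def _within_ss_from_points(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(w)


def ward_cluster(D: np.ndarray, k: int) -> ClusterSolution:
    """Cut a Ward's-method dendrogram of the dissimilarities at k clusters."""
    D = _check_dissimilarity(D)
    n = len(D)
    if k < 1 or k > n:
        raise ValueError("k must be in [1, n]")
    Z = linkage(squareform(D, checks=False), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterSolution(k, labels, _within_ss_from_D(D, labels), "ward")


def _kmeans_W(X: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, float]:
    if k >= len(X):
        return np.arange(len(X)), 0.0
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return km.labels_, float(km.inertia_)


def elbow_profile(coordinates: np.ndarray, k_max: int, seed: int = 0):
    """(k, W_k) profile from k-means plus the elbow-suggested k.

    The suggested k maximises the second difference W_{k-1} - 2 W_k + W_{k+1}
    over 2 <= k <= k_max - 1.  A "distinct" elbow requires the profile to
    collapse somewhere (some W_{k+1}/W_k < 0.2); smooth power-law-like
    profiles (e.g. collinear equidistant points) have no distinct elbow and
    fall back to the first k whose W_k drops below 10% of W_1.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k_max < 3:
        raise ValueError("k_max must be >= 3 to locate an elbow")
    k_max = min(k_max, len(X))
    ks = np.arange(1, k_max + 1)
    W = np.array([_kmeans_W(X, k, seed)[1] for k in ks])
    if W[0] == 0.0:  # degenerate: all points identical
        return list(zip(ks.tolist(), W.tolist())), 1
    second = W[:-2] - 2 * W[1:-1] + W[2:]  # indexed by k = 2..k_max-1
    ratios = W[1:] / np.where(W[:-1] > 0, W[:-1], 1.0)
    distinct = bool(second.size) and bool((ratios < 0.2).any())
    if distinct:
        suggested = int(np.argmax(second) + 2)
    else:
        below = np.flatnonzero(W < 0.10 * W[0])
        suggested = int(ks[below[0]]) if below.size else int(k_max)
    return list(zip(ks.tolist(), W.tolist())), suggested


def gap_statistic(coordinates: np.ndarray, k_max: int, B: int = 50,
                  seed: int = 0) -> GapResult:
    """Tibshirani's gap statistic with a uniform bounding-box reference.

    Gap(k) = mean_b log W_k(ref_b) - log W_k(data); s_k is the reference
    standard deviation scaled by sqrt(1 + 1/B).  chosen_k is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1} (k_max if the rule never fires).
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if B < 10:
        raise ValueError("B must be >= 10")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate (zero-variance) data")
    k_max = min(k_max, len(X) - 1)
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = np.arange(1, k_max + 1)

    logW = np.empty(k_max)
    for i, k in enumerate(ks):
        logW[i] = np.log(max(_kmeans_W(X, k, seed)[1], 1e-300))

    logW_ref = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2 ** 31 - 1))
        for i, k in enumerate(ks):
            logW_ref[b, i] = np.log(max(_kmeans_W(ref, k, ref_seed)[1], 1e-300))

    gap = logW_ref.mean(axis=0) - logW
    s = logW_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = int(ks[i])
            break
    return GapResult(ks, gap, s, B, chosen)


def two_step(D: np.ndarray, k_max: int = 8, B: int = 50, seed: int = 0,
             embed_dim: int = 2, use_embedding: bool = True) -> ClusterSolution:
    """Ward-then-k-means clustering with consensus k selection.

    k comes from the gap statistic; if the elbow criterion disagrees by
    exactly one cluster the larger of the two is preferred (a significant
    residual drop in W is taken seriously).  k-means is initialised at the
    Ward-cut cluster means — its only initialisation, keeping the routine
    deterministic.  With ``use_embedding=False`` the refinement runs on a
    full-rank embedding of D rather than the plotted 2-D face space.
    """
    D = _check_dissimilarity(D)
    n = len(D)
    if n < 3:
        raise ValueError("need at least 3 exemplars")
    k_max = min(k_max, n - 1)
    dim = embed_dim if use_embedding else min(n - 1, D.shape[0])
    X = mds_embed(D, dim=dim)

    if np.allclose(X.var(axis=0), 0.0):
        labels = np.zeros(n, dtype=int)
        return ClusterSolution(1, labels, 0.0, "two_step",
                               {"k_gap": 1, "k_elbow": 1, "k_used": 1})

    gap = gap_statistic(X, k_max=k_max, B=B, seed=seed)
    profile, k_elbow = elbow_profile(X, k_max=max(k_max, 3), seed=seed)
    k = gap.chosen_k
    if abs(k_elbow - k) == 1:
        k = max(k_elbow, k)

    ward = ward_cluster(D, k)
    means = np.vstack([X[ward.labels == c].mean(axis=0) for c in range(k)])
    if k >= n:
        labels, W = np.arange(n), 0.0
    else:
        km = KMeans(n_clusters=k, init=means, n_init=1).fit(X)
        labels, W = km.labels_, float(km.inertia_)
    diagnostics = {
        "k_gap": gap.chosen_k,
        "k_elbow": k_elbow,
        "k_used": k,
        "ward_within_ss": _within_ss_from_points(X, ward.labels),
        "elbow_profile": profile,
        "gap_table": [
            {"k": int(kk), "gap": float(g), "s": float(ss)}
            for kk, g, ss in zip(gap.ks, gap.gap, gap.s)
        ],
    }
    return ClusterSolution(int(k), labels, W, "two_step", diagnostics)


def flag_outliers(solution: ClusterSolution, coordinates: np.ndarray,
                  ids: list[str] | None = None) -> list:
    """Members of singleton clusters that are far from everything else.

    "Far" means the point's nearest-neighbour distance exceeds the 95th
    percentile of all nearest-neighbour distances in the embedding.
    """
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ids = ids if ids is not None else list(range(len(X)))
    labels = solution.labels
    if len(X) < 2:
        return []
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    cutoff = np.percentile(nn, 95)
    out = []
    for lab in range(solution.k):
        idx = np.flatnonzero(labels == lab)
        if len(idx) == 1 and nn[idx[0]] > cutoff:
            out.append(ids[idx[0]])
    return out
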