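"""Connectivity-based parcellation of a seed region.

Seed-ROI voxels are clustered by the similarity of their whole-brain
connectivity rows using k-means under the correlation distance
d(x, y) = 1 - Pearson r(x, y).  Rows are standardized (centered, unit norm
across targets), which makes 1 - r a monotone function of squared Euclidean
distance, so Lloyd updates remain valid; centroids are re-standardized means
of their member rows.

Cluster-vs-anatomy agreement is quantified by the proportion of each
cluster's voxels falling in each anatomical region, with significance from a
voxel-label permutation test: the null mean and SD are obtained by a Gaussian
fit to the permuted proportions, z = (observed - mean) / sd, one-sided normal
p, and Benjamini-Hochberg FDR across all cluster x region cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, _standardize_rows


@dataclass
class ParcellationResult:
    labels: np.ndarray               # 1..k per ROI voxel, canonical voxel order
    k: int
    n_init: int
    rng_seed: int
    total_within_cluster_distance: float
    n_iter: int = 0
    init_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError("labels must cover 1..k with every cluster nonempty")


@dataclass
class OverlapTable:
    """Cluster x anatomical-region overlap with permutation inference."""

    proportions: np.ndarray          # (k, C), rows sum to 1
    z_scores: np.ndarray | None = None
    p_values: np.ndarray | None = None          # one-sided, from the normal fit
    p_empirical: np.ndarray | None = None
    fdr_q: np.ndarray | None = None
    flagged: np.ndarray | None = None            # cells with degenerate null sd
    permutations: int = 0
    cluster_names: list[str] = field(default_factory=list)
    region_names: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        k, c = self.proportions.shape
        cl = self.cluster_names or [f"cluster_{i + 1}" for i in range(k)]
        rg = self.region_names or [f"region_{j + 1}" for j in range(c)]
        rows = []
        for i in range(k):
            for j in range(c):
                rows.append({
                    "cluster": cl[i], "region": rg[j],
                    "proportion": self.proportions[i, j],
                    "z": None if self.z_scores is None else self.z_scores[i, j],
                    "p": None if self.p_values is None else self.p_values[i, j],
                    "q": None if self.fdr_q is None else self.fdr_q[i, j],
                })
        return pd.DataFrame(rows)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def _corr_dist(rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - r between standardized rows and standardized centroids."""
    return 1.0 - rows @ centroids.T


def _standardize_centroids(c: np.ndarray) -> np.ndarray:
    c = c - c.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate (constant) centroid")
    return c / norms


def _kmeanspp_init(rows: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under correlation distance; returns row indices."""
    n = rows.shape[0]
    idx = [int(rng.integers(n))]
    d = _corr_dist(rows, rows[idx]).ravel()
    for _ in range(1, k):
        w = np.maximum(d, 0.0) ** 2
        total = w.sum()
        if total == 0:
            cand = int(rng.integers(n))
        else:
            cand = int(rng.choice(n, p=w / total))
        idx.append(cand)
        d = np.minimum(d, _corr_dist(rows, rows[[cand]]).ravel())
    return np.asarray(idx)


def _lloyd(rows: np.ndarray, centroids: np.ndarray, max_iter: int) -> tuple[np.ndarray, float, int]:
    """Lloyd iterations from given standardized centroids.

    Empty clusters are re-seeded from the row farthest from its centroid.
    Returns (0-based labels, total within-cluster distance, iterations)."""
    k = centroids.shape[0]
    labels = np.full(rows.shape[0], -1)
    for it in range(1, max_iter + 1):
        d = _corr_dist(rows, centroids)
        new_labels = d.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(d[np.arange(len(rows)), new_labels].argmax())
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        means = np.stack([rows[labels == c].mean(axis=0) for c in range(k)])
        centroids = _standardize_centroids(means)
    d = _corr_dist(rows, centroids)
    inertia = float(d[np.arange(len(rows)), labels].sum())
    return labels, inertia, it


def kmeans_correlation(
    matrix: ConnectivityMatrix,
    k: int,
    n_init: int = 10,
    rng_seed: int = 0,
    max_iter: int = 300,
    init_indices: np.ndarray | None = None,
) -> ParcellationResult:
    """Correlation-distance k-means on connectivity rows.

    Best of ``n_init`` k-means++ restarts by total within-cluster distance;
    deterministic given ``rng_seed``.  ``init_indices`` overrides seeding
    with explicit row indices (single run), used for cross-checking against
    reference implementations.
    """
    rows_raw = matrix.values
    if k < 2:
        raise ValueError("k must be >= 2")
    if rows_raw.shape[0] <= k:
        raise ValueError("need more ROI voxels than clusters")
    if np.any(rows_raw.std(axis=1) == 0):
        raise ValueError("constant connectivity rows cannot be standardized")
    rows = _standardize_rows(rows_raw)
    rng = np.random.default_rng(rng_seed)

    best = None
    if init_indices is not None:
        inits = [np.asarray(init_indices)]
    else:
        inits = [_kmeanspp_init(rows, k, rng) for _ in range(n_init)]
    for idx in inits:
        labels, inertia, n_iter = _lloyd(rows, rows[idx], max_iter)
        if best is None or inertia < best[1] - 1e-12:
            best = (labels, inertia, n_iter, idx)
    labels, inertia, n_iter, idx = best
    return ParcellationResult(labels + 1, k=k, n_init=len(inits), rng_seed=rng_seed,
                              total_within_cluster_distance=inertia, n_iter=n_iter,
                              init_indices=idx)


def _count_matrix(cluster_labels: np.ndarray, anat_labels: np.ndarray,
                  k: int, n_regions: int) -> np.ndarray:
    flat = (cluster_labels - 1) * n_regions + (anat_labels - 1)
    return np.bincount(flat, minlength=k * n_regions).reshape(k, n_regions)


def overlap_proportions(parcellation: ParcellationResult,
                        anat_labels: np.ndarray,
                        region_names: list[str] | None = None) -> OverlapTable:
    """Proportion of each cluster's voxels inside each anatomical region.

    ``anat_labels`` is the per-ROI-voxel anatomical label (1..C) in the same
    canonical voxel order as the parcellation labels; every ROI voxel must be
    labeled (label 0 is an error).
    """
    anat = np.asarray(anat_labels, dtype=np.int32)
    if anat.shape != parcellation.labels.shape:
        raise ValueError("anatomical labels must align with ROI voxels")
    if np.any(anat < 1):
        raise ValueError("ROI voxel with anatomical label 0 (unlabeled)")
    c = int(anat.max())
    counts = _count_matrix(parcellation.labels, anat, parcellation.k, c)
    props = counts / counts.sum(axis=1, keepdims=True)
    return OverlapTable(proportions=props, region_names=region_names or [])


def permutation_zscore(
    table: OverlapTable,
    parcellation: ParcellationResult,
    anat_labels: np.ndarray,
    n_perm: int = 10000,
    rng_seed: int = 0,
    fdr_alpha: float = 0.05,
) -> OverlapTable:
    """Permutation inference on the overlap proportions.

    Anatomical labels are shuffled across ROI voxels; each permutation's
    proportion matrix contributes to a null per cell.  The null mean and SD
    come from a Gaussian fit (sample mean, unbiased SD) to the permuted
    proportions; z = (observed - mean) / sd, one-sided normal-tail p, an
    empirical tail p for robustness, and Benjamini-Hochberg q across all
    cluster x region cells.  Cells with a degenerate (zero-SD) null are
    flagged rather than assigned infinite z.
    """
    if n_perm < 1000:
        raise ValueError("use at least 1000 permutations")
    anat = np.asarray(anat_labels, dtype=np.int32)
    k, c = table.proportions.shape
    n = len(anat)
    rng = np.random.default_rng(rng_seed)
    cl0 = parcellation.labels - 1
    cluster_sizes = np.bincount(cl0, minlength=k).astype(float)

    perm = rng.permuted(np.tile(anat, (n_perm, 1)), axis=1)           # (P, n)
    flat = (np.arange(n_perm)[:, None] * (k * c)
            + cl0[None, :] * c + (perm - 1))
    counts = np.bincount(flat.ravel(), minlength=n_perm * k * c)
    null_props = counts.reshape(n_perm, k, c) / cluster_sizes[None, :, None]

    mean = null_props.mean(axis=0)
    sd = null_props.std(axis=0, ddof=1)
    flagged = sd == 0
    z = np.full((k, c), np.nan)
    z[~flagged] = (table.proportions[~flagged] - mean[~flagged]) / sd[~flagged]
    p = np.full((k, c), np.nan)
    p[~flagged] = stats.norm.sf(z[~flagged])
    p_emp = (1 + (null_props >= table.proportions[None, :, :]).sum(axis=0)) / (1 + n_perm)

    q = np.full((k, c), np.nan)
    ok = ~flagged
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return OverlapTable(
        proportions=table.proportions, z_scores=z, p_values=p,
        p_empirical=p_emp, fdr_q=q, flagged=flagged, permutations=n_perm,
        cluster_names=table.cluster_names, region_names=table.region_names,
    )


def match_clusters(parcellation: ParcellationResult,
                   anat_labels: np.ndarray) -> dict[int, int]:
    """One-to-one cluster -> region assignment maximizing total overlap.

    Optimal assignment on the k x C count matrix; ties broken toward the
    lowest region index.
    """
    anat = np.asarray(anat_labels, dtype=np.int32)
    c = int(anat.max())
    counts = _count_matrix(parcellation.labels, anat, parcellation.k, c).astype(float)
    cost = -counts + 1e-9 * np.arange(c)[None, :]   # tie-break: lowest region
    rows, cols = linear_sum_assignment(cost)
    return {int(r + 1): int(col + 1) for r, col in zip(rows, cols)}


def k_sweep(
    matrix: ConnectivityMatrix,
    anat_labels: np.ndarray,
    ks: list[int] = (3, 4, 5, 6),
    n_init: int = 10,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> dict[int, tuple[ParcellationResult, OverlapTable]]:
    """Run the parcellation + overlap inference over a range of k values."""
    out = {}
    for k in ks:
        parc = kmeans_correlation(matrix, k, n_init=n_init, rng_seed=rng_seed)
        tab = overlap_proportions(parc, anat_labels)
        tab = permutation_zscore(tab, parc, anat_labels, n_perm=n_perm, rng_seed=rng_seed)
        out[k] = (parc, tab)
    return out
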