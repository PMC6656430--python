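"""Shared fixtures and independent reference oracles.

The oracles here deliberately re-derive each quantity by the most direct
route available (explicit loops, flood fill, exhaustive enumeration) so they
stay independent of the vectorized implementation paths they check.
"""

from collections import deque
from itertools import product

import numpy as np
import pytest

import olfparc


@pytest.fixture(scope="session")
def small_dataset():
    """Six subjects on a 16x16x12 grid, T=200, rho=0.5 — shared read-only."""
    spec = olfparc.scaled_spec((16, 16, 12), n_subjects=6, n_timepoints=200,
                               within_network_corr=0.5, rng_seed=11)
    return olfparc.generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def roi_vector(volume, mask):
    """Values of ``volume`` over ``mask`` in the canonical voxel ordering."""
    coords = olfparc.volume.mask_coordinates(mask)
    return volume[coords[:, 0], coords[:, 1], coords[:, 2]]


# --------------------------------------------------------------------------
# reference oracles
# --------------------------------------------------------------------------

def tfce_bruteforce(stat, E, H, n_steps, neighbourhood=26, h_max=None):
    """TFCE by explicit per-threshold flood-fill component labelling."""
    stat = np.asarray(stat, dtype=float)
    out = np.zeros_like(stat)
    if h_max is None:
        h_max = stat.max()
    if h_max <= 0:
        return out
    dh = h_max / n_steps
    if neighbourhood == 6:
        offsets = [o for o in product((-1, 0, 1), repeat=3)
                   if sum(map(abs, o)) == 1]
    elif neighbourhood == 18:
        offsets = [o for o in product((-1, 0, 1), repeat=3)
                   if 1 <= sum(map(abs, o)) <= 2]
    else:
        offsets = [o for o in product((-1, 0, 1), repeat=3) if any(o)]
    shape = stat.shape
    for step in range(1, n_steps + 1):
        h = step * dh
        supra = stat >= h
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            # flood fill one component
            comp = []
            q = deque([start])
            seen[start] = True
            while q:
                v = q.popleft()
                comp.append(v)
                for o in offsets:
                    w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                    if all(0 <= w[i] < shape[i] for i in range(3)) \
                            and supra[w] and not seen[w]:
                        seen[w] = True
                        q.append(w)
            contrib = (len(comp) ** E) * (h ** H) * dh
            for v in comp:
                out[v] += contrib
    return out


def lloyd_reference(rows_std, init_indices, max_iter=300):
    """Plain-loop k-means under correlation distance from given init rows.

    Standardized rows; distance via np.corrcoef per pair; centroids are
    member means re-centered and re-normalized.  Empty clusters re-seeded
    from the row farthest from its assigned centroid (same documented policy,
    independent realization)."""
    k = len(init_indices)
    cents = rows_std[list(init_indices)].copy()
    n = rows_std.shape[0]
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = np.empty((n, k))
        for i in range(n):
            for c in range(k):
                d[i, c] = 1.0 - np.corrcoef(rows_std[i], cents[c])[0, 1]
        new = d.argmin(axis=1)
        for c in range(k):
            if not (new == c).any():
                far = int(d[np.arange(n), new].argmax())
                new[far] = c
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(k):
            m = rows_std[labels == c].mean(axis=0)
            m = m - m.mean()
            cents[c] = m / np.linalg.norm(m)
    return labels


def loo_stability_bruteforce(matrices):
    """Leave-one-out stability by direct loops over subjects and voxels."""
    n = len(matrices)
    n_vox = matrices[0].values.shape[0]
    out = np.zeros(n_vox)
    for v in range(n_vox):
        acc = 0.0
        for i in range(n):
            zs = [np.arctanh(np.clip(m.values[v], -1 + 1e-6, 1 - 1e-6))
                  for j, m in enumerate(matrices) if j != i]
            grp = np.tanh(np.mean(zs, axis=0))
            acc += np.corrcoef(matrices[i].values[v], grp)[0, 1]
        out[v] = acc / n
    return out


def assignment_bruteforce(counts):
    """Best one-to-one cluster->region map by exhaustive k! enumeration."""
    from itertools import permutations

    k, c = counts.shape
    best, best_total = None, -np.inf
    for perm in permutations(range(c), k):
        total = sum(counts[i, perm[i]] for i in range(k))
        if total > best_total:
            best, best_total = perm, total
    return {i + 1: best[i] + 1 for i in range(k)}
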