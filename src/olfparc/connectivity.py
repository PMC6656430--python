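"""Seed-to-whole-brain voxelwise connectivity.

Builds, for each subject, the matrix of Pearson correlations between every
voxel in a seed region of interest and every brain voxel outside it; provides
Fisher-z group averaging and the leave-one-out inter-subject stability map
that justifies (or not) averaging connectivity across subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .volume import Bold4D, check_mask, mask_coordinates, series_at


@dataclass
class ConnectivityMatrix:
    """Seed-voxel x target-voxel connectivity for one subject (or a group).

    ``scale`` is ``"r"`` for Pearson correlations (entries in [-1, 1]) or
    ``"z"`` after the Fisher transform (unbounded).  Voxel coordinate index
    maps make the matrix layout explicit and reproducible.
    """

    values: np.ndarray
    roi_index: np.ndarray      # (n_roi, 3) voxel coordinates
    target_index: np.ndarray   # (n_targets, 3)
    subject_id: str = ""
    scale: str = "r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.roi_index), len(self.target_index)):
            raise ValueError("values shape does not match index maps")
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        if self.scale == "r":
            if np.any(np.isnan(self.values)):
                raise ValueError("r-scale matrix contains NaNs")
            if np.any(np.abs(self.values) > 1.0 + 1e-12):
                raise ValueError("r-scale matrix has entries outside [-1, 1]")

    def same_indices(self, other: "ConnectivityMatrix") -> bool:
        return np.array_equal(self.roi_index, other.roi_index) and np.array_equal(
            self.target_index, other.target_index
        )

    def save(self, path: str | Path) -> None:
        """Persist as .npz plus a JSON index sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values,
                            roi_index=self.roi_index, target_index=self.target_index)
        sidecar = {
            "subject_id": self.subject_id,
            "scale": self.scale,
            "coordinate_convention": "0-based voxel indices, x fastest",
            "n_roi": int(len(self.roi_index)),
            "n_targets": int(len(self.target_index)),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(arrays["values"], arrays["roi_index"], arrays["target_index"],
                   subject_id=meta["subject_id"], scale=meta["scale"])


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm (for correlation by dot product)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    return xc / norms


def voxelwise_connectivity(bold: Bold4D, roi_mask: np.ndarray,
                           brain_mask: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson r between each ROI voxel and every brain voxel outside the ROI.

    The target set is the brain mask minus the ROI, so a voxel is never
    correlated with itself.  Zero-variance voxels are an error (their
    correlation is undefined) and are reported with their coordinates.
    """
    shape = bold.grid_shape
    roi_mask = check_mask(roi_mask, shape, "roi_mask")
    brain_mask = check_mask(brain_mask, shape, "brain_mask")
    target_mask = brain_mask & ~roi_mask
    if not roi_mask.any() or not target_mask.any():
        raise ValueError("ROI or target mask is empty")
    roi_index = mask_coordinates(roi_mask)
    target_index = mask_coordinates(target_mask)
    roi_ts = series_at(bold.data, roi_index)
    tgt_ts = series_at(bold.data, target_index)
    for name, ts, idx in (("ROI", roi_ts, roi_index), ("target", tgt_ts, target_index)):
        sd = ts.std(axis=1)
        if np.any(sd == 0):
            bad = idx[sd == 0]
            raise ValueError(f"zero-variance {name} voxels at {bad[:5].tolist()}")
    r = _standardize_rows(roi_ts) @ _standardize_rows(tgt_ts).T
    np.clip(r, -1.0, 1.0, out=r)
    return ConnectivityMatrix(r, roi_index, target_index, subject_id, scale="r")


def fisher_z(values: np.ndarray, direction: str = "forward",
             clip: float | None = None) -> np.ndarray:
    """Fisher variance-stabilizing transform z = atanh(r) and its inverse.

    ``clip`` (forward only) caps |r| at the given value instead of raising
    on |r| >= 1; the default is to raise.
    """
    values = np.asarray(values, dtype=np.float64)
    if direction == "forward":
        if clip is not None:
            values = np.clip(values, -clip, clip)
        elif np.any(np.abs(values) >= 1.0):
            raise ValueError("|r| >= 1: Fisher z undefined (pass clip= to cap)")
        return np.arctanh(values)
    if direction == "inverse":
        return np.tanh(values)
    raise ValueError("direction must be 'forward' or 'inverse'")


def group_average(matrices: list[ConnectivityMatrix],
                  clip: float = 1.0 - 1e-6) -> ConnectivityMatrix:
    """Fisher-z average across subjects, returned on the r scale.

    Entrywise tanh(mean(atanh(r_s))) — the variance-stabilized mean, invariant
    to subject order.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if not m.same_indices(first):
            raise ValueError(f"index mismatch between subjects {first.subject_id!r} and {m.subject_id!r}")
        if m.scale != "r":
            raise ValueError("group_average expects r-scale matrices")
    z = np.mean([fisher_z(m.values, clip=clip) for m in matrices], axis=0)
    return ConnectivityMatrix(np.tanh(z), first.roi_index, first.target_index,
                              subject_id="group", scale="r")


def loo_stability(matrices: list[ConnectivityMatrix],
                  clip: float = 1.0 - 1e-6) -> np.ndarray:
    """Leave-one-out inter-subject stability, one value per ROI voxel.

    For each held-out subject, the remaining subjects' matrices are
    Fisher-z averaged; stability of voxel v is the Pearson correlation
    (across target voxels, r-scale rows) between the held-out subject's row
    and the group row, averaged over held-out subjects.
    """
    n = len(matrices)
    if n < 3:
        raise ValueError("leave-one-out stability needs at least 3 subjects")
    first = matrices[0]
    for m in matrices[1:]:
        if not m.same_indices(first):
            raise ValueError("index mismatch across subjects")
    z = np.stack([fisher_z(m.values, clip=clip) for m in matrices])  # (N, V, T)
    z_sum = z.sum(axis=0)
    acc = np.zeros(z.shape[1])
    for i in range(n):
        group_r = np.tanh((z_sum - z[i]) / (n - 1))
        subj_r = matrices[i].values
        a = subj_r - subj_r.mean(axis=1, keepdims=True)
        b = group_r - group_r.mean(axis=1, keepdims=True)
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        if np.any(na == 0) or np.any(nb == 0):
            raise ValueError("zero-variance connectivity row; stability undefined")
        acc += (a * b).sum(axis=1) / (na * nb)
    return acc / n


def stability_threshold(n_targets: int, n_roi: int, alpha: float = 0.05) -> float:
    """Critical |r| for one ROI voxel's stability, Bonferroni over ROI voxels.

    Derived from the exact t-transform of a correlation over ``n_targets``
    observations: t = r sqrt(df / (1 - r^2)), df = n_targets - 2; one-sided
    positive test at level alpha / n_roi.
    """
    if n_targets < 3 or n_roi < 1:
        raise ValueError("need n_targets >= 3 and n_roi >= 1")
    df = n_targets - 2
    t_crit = stats.t.ppf(1.0 - alpha / n_roi, df)
    return float(t_crit / np.sqrt(df + t_crit ** 2))
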