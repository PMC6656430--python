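"""Group-level inference on seed connectivity maps.

Per-subject seed maps (Fisher-z of the correlation between a seed region's
mean time series and every brain voxel) are tested against zero with a
one-sample sign-flipping permutation test.  Multiple comparisons are handled
by threshold-free cluster enhancement (TFCE): each voxel's statistic is
replaced by an integral over cluster extent^E x height^H across all
thresholds, and family-wise error is controlled with the max-TFCE null
distribution over sign flips.

Also provides the unique/common network decomposition of several seeds'
significance masks, atlas volume tables, and the lateralization index
LI = (Z_left - Z_right) / (Z_left + Z_right).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import smooth_gaussian
from .volume import Bold4D, check_mask, mask_coordinates, series_at
from .connectivity import fisher_z


@dataclass
class SubjectZMap:
    """One subject's Fisher-z seed connectivity map on a brain grid."""

    zmap: np.ndarray            # 3D, zero outside valid_mask
    valid_mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.zmap = np.asarray(self.zmap, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.zmap.shape != self.valid_mask.shape:
            raise ValueError("zmap and valid_mask shapes differ")
        if not np.all(np.isfinite(self.zmap[self.valid_mask])):
            raise ValueError("non-finite z values inside the valid mask")


@dataclass
class TFCEParams:
    """TFCE settings: extent exponent E, height exponent H, threshold steps,
    and the 3D connected-component neighbourhood (6, 18 or 26)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity_neighbourhood: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be nonnegative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity_neighbourhood not in (6, 18, 26):
            raise ValueError("neighbourhood must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity_neighbourhood]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class GroupStatResult:
    t_map: np.ndarray
    tfce_map: np.ndarray
    fwe_p_map: np.ndarray
    sig_mask: np.ndarray
    n_permutations: int
    rng_seed: int
    alpha: float
    mask: np.ndarray = field(default=None)


@dataclass
class LateralizationMap:
    """Smoothed per-voxel LI with its validity mask (|Z_L + Z_R| > eps)."""

    li: np.ndarray
    valid_mask: np.ndarray


def seed_zmap(bold: Bold4D, seed_mask: np.ndarray, brain_mask: np.ndarray,
              subject_id: str = "", clip: float = 1.0 - 1e-6) -> SubjectZMap:
    """Fisher-z map of the seed's mean time series against every brain voxel.

    Targets are brain-mask voxels outside the seed.  Correlations are clipped
    at ``clip`` before atanh so degenerate (perfectly correlated) voxels stay
    finite; clipping is reported as a warning.
    """
    shape = bold.grid_shape
    seed_mask = check_mask(seed_mask, shape, "seed_mask")
    brain_mask = check_mask(brain_mask, shape, "brain_mask")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    target_mask = brain_mask & ~seed_mask
    seed_coords = mask_coordinates(seed_mask)
    seed_mean = series_at(bold.data, seed_coords).mean(axis=0)
    if seed_mean.std() == 0:
        raise ValueError("seed average time series is constant")
    tgt_coords = mask_coordinates(target_mask)
    tgt = series_at(bold.data, tgt_coords)
    sm = seed_mean - seed_mean.mean()
    tc = tgt - tgt.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(tc, axis=1) * np.linalg.norm(sm)
    if np.any(denom == 0):
        bad = tgt_coords[np.linalg.norm(tc, axis=1) == 0]
        raise ValueError(f"zero-variance target voxels at {bad[:5].tolist()}")
    r = (tc @ sm) / denom
    if np.any(np.abs(r) > clip):
        warnings.warn(f"{int((np.abs(r) > clip).sum())} correlations clipped at |r|={clip}")
    z = fisher_z(r, clip=clip)
    zvol = np.zeros(shape)
    zvol[tgt_coords[:, 0], tgt_coords[:, 1], tgt_coords[:, 2]] = z
    return SubjectZMap(zvol, target_mask, subject_id)


def tfce(stat_map: np.ndarray, params: TFCEParams = TFCEParams(),
         h_max: float | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    TFCE(p) = sum over h in {dh, 2dh, ..., h_max} of e(h, p)^E * h^H * dh,
    where e(h, p) is the voxel count of the connected component containing p
    in the supra-threshold set {stat >= h}, and dh = h_max / n_steps.
    Negative values contribute nothing (positive-contrast enhancement);
    an all-nonpositive map returns all zeros.

    ``h_max`` defaults to the map's maximum.  Pass a fixed value to keep the
    threshold grid identical across maps (TFCE is then pointwise monotone in
    the input; with the adaptive grid, monotonicity holds only up to
    discretization).
    """
    stat = np.asarray(stat_map, dtype=np.float64)
    if stat.ndim != 3:
        raise ValueError("stat_map must be 3D")
    if not np.all(np.isfinite(stat)):
        raise ValueError("stat_map contains non-finite values")
    out = np.zeros_like(stat)
    if h_max is None:
        h_max = stat.max()
    if h_max <= 0:
        return out
    dh = h_max / params.n_steps
    structure = params.structure
    for step in range(1, params.n_steps + 1):
        h = step * dh
        supra = stat >= h
        if not supra.any():
            break
        lab, n_comp = ndimage.label(supra, structure=structure)
        sizes = np.bincount(lab.ravel())
        extent = sizes[lab[supra]]
        out[supra] += (extent.astype(np.float64) ** params.E) * (h ** params.H) * dh
    return out


def _all_sign_patterns(n: int) -> np.ndarray:
    bits = ((np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1)
    return 1.0 - 2.0 * bits    # first row is the identity (all +1)


def _flip_tmaps(x: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics of every sign-flipped dataset, vectorized.

    ``x`` is (N, V); ``signs`` (F, N).  The per-voxel mean square is
    invariant under flips, so only the mean changes."""
    n = x.shape[0]
    msq = (x ** 2).mean(axis=0)
    mean = signs @ x / n
    var = np.maximum((msq[None, :] - mean ** 2) * n / (n - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def signflip_ttest(
    zmaps: list[SubjectZMap] | np.ndarray,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 10000,
    alpha: float = 0.001,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
    two_sided: bool = False,
) -> GroupStatResult:
    """One-sample sign-flipping permutation test with TFCE-based FWE control.

    Under the symmetric null each subject's map may be multiplied by +-1.
    The null distribution is the maximum TFCE score over the brain for each
    of ``n_perm`` flip patterns (the identity flip always among them; all
    2^N patterns are enumerated when 2^N <= n_perm), and
    fwe_p(v) = #{null_max >= tfce_obs(v)} / n_perm.  One-sided positive by
    default; ``two_sided=True`` enhances |t| instead (for difference maps
    such as the lateralization index).
    """
    if isinstance(zmaps, np.ndarray):
        stack = np.asarray(zmaps, dtype=np.float64)
        if mask is None:
            raise ValueError("mask required when passing a raw array stack")
    else:
        if mask is None:
            mask = zmaps[0].valid_mask.copy()
            for m in zmaps[1:]:
                mask &= m.valid_mask
        stack = np.stack([m.zmap for m in zmaps])
    n = stack.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for sign-flipping inference")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    x = stack[:, mask]                      # (N, V)

    zero_var = x.std(axis=0) == 0
    if zero_var.any() and not np.all(x[:, zero_var] == 0):
        warnings.warn(f"{int(zero_var.sum())} zero-variance voxels excluded from TFCE")

    if 2 ** n <= n_perm:
        signs = _all_sign_patterns(n)
        n_perm = signs.shape[0]
    else:
        rng = np.random.default_rng(rng_seed)
        signs = 1.0 - 2.0 * rng.integers(0, 2, size=(n_perm, n)).astype(np.float64)
        signs[0] = 1.0                     # identity flip always included

    tmaps = _flip_tmaps(x, signs)
    if two_sided:
        tmaps_enh = np.abs(tmaps)
    else:
        tmaps_enh = tmaps

    tvol = np.zeros(shape)
    null_max = np.empty(n_perm)
    obs_tfce_flat = None
    for f in range(n_perm):
        tvol[:] = 0.0
        tvol[mask] = tmaps_enh[f]
        tf = tfce(tvol, params)
        null_max[f] = tf.max()
        if f == 0:
            obs_tfce_flat = tf[mask].copy()
            obs_tfce_vol = tf

    counts = (null_max[None, :] >= obs_tfce_flat[:, None]).sum(axis=1)
    fwe_p = counts / n_perm
    t_map = np.zeros(shape)
    t_map[mask] = tmaps[0]
    fwe_vol = np.ones(shape)
    fwe_vol[mask] = fwe_p
    sig = np.zeros(shape, dtype=bool)
    sig[mask] = fwe_p < alpha
    return GroupStatResult(t_map=t_map, tfce_map=obs_tfce_vol, fwe_p_map=fwe_vol,
                           sig_mask=sig, n_permutations=n_perm, rng_seed=rng_seed,
                           alpha=alpha, mask=mask)


def unique_common_masks(
    results: dict[str, GroupStatResult],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Decompose several seeds' significance masks into unique and common parts.

    unique[s] marks voxels significant for seed s and no other; the common
    mask marks voxels significant for every seed.  Every significant voxel
    therefore belongs to exactly one of: some unique mask, the common mask,
    or the shared-but-not-all remainder.
    """
    names = list(results)
    if not names:
        raise ValueError("no results to decompose")
    shape = results[names[0]].sig_mask.shape
    for nm in names:
        if results[nm].sig_mask.shape != shape:
            raise ValueError(f"grid mismatch for seed {nm!r}")
    stack = np.stack([results[nm].sig_mask for nm in names])
    n_sig = stack.sum(axis=0)
    unique = {nm: stack[i] & (n_sig == 1) for i, nm in enumerate(names)}
    common = n_sig == len(names)
    return unique, common


def atlas_volume_table(mask: np.ndarray, atlas_labels: np.ndarray,
                       voxel_volume_mm3: float, min_volume_mm3: float = 80.0,
                       label_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-atlas-region volume of a binary mask, small entries suppressed.

    Volume = voxel count x voxel volume; regions whose overlap is below
    ``min_volume_mm3`` are retained in the table but marked suppressed
    (reported as "-" in print-outs).
    """
    mask = np.asarray(mask, dtype=bool)
    atlas = np.asarray(atlas_labels)
    if atlas.shape != mask.shape:
        raise ValueError("atlas labels must share the mask's grid")
    labels = np.unique(atlas[mask & (atlas > 0)])
    rows = []
    for lab in labels:
        count = int(((atlas == lab) & mask).sum())
        vol = count * voxel_volume_mm3
        rows.append({
            "label": int(lab),
            "region": (label_names or {}).get(int(lab), f"region_{int(lab)}"),
            "n_voxels": count,
            "volume_mm3": vol,
            "suppressed": vol < min_volume_mm3,
        })
    return pd.DataFrame(rows, columns=["label", "region", "n_voxels", "volume_mm3", "suppressed"])


def lateralization_index(z_left: np.ndarray, z_right: np.ndarray,
                         affine: np.ndarray, sigma_mm: float = 3.0,
                         eps: float = 1e-6) -> LateralizationMap:
    """LI = (Z_left - Z_right) / (Z_left + Z_right), spatially smoothed.

    Valid only where |Z_left + Z_right| > eps; invalid voxels are set to 0
    before smoothing.  Where both inputs are nonnegative and valid the raw
    LI lies in [-1, 1]; swapping inputs negates it exactly (pre-smoothing).
    """
    zl = np.asarray(z_left, dtype=np.float64)
    zr = np.asarray(z_right, dtype=np.float64)
    if zl.shape != zr.shape:
        raise ValueError("left/right maps must share a grid")
    denom = zl + zr
    valid = np.abs(denom) > eps
    li = np.zeros_like(zl)
    li[valid] = (zl[valid] - zr[valid]) / denom[valid]
    if sigma_mm > 0:
        li = smooth_gaussian(li, sigma_mm, affine)
    return LateralizationMap(li=li, valid_mask=valid)
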