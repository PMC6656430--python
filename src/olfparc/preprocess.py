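"""Signal cleaning for gridded 4D data.

Covers the post-registration steps of a standard resting-state pipeline:
polynomial detrending, nuisance (confound) regression, global intensity
normalization, temporal band-pass filtering and spatial Gaussian smoothing.
Every step is a pure function of its inputs — identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Bold4D

GRAND_MEAN = 10000.0


class NuisanceSet:
    """Confound time series, one column per regressor (t x q).

    Typical contents: six head-movement parameters plus white-matter and
    CSF mean signals.  Columns must not be identically zero.
    """

    def __init__(self, matrix: np.ndarray, names: list[str] | None = None):
        m = np.asarray(matrix, dtype=np.float64)
        if m.ndim == 1:
            m = m[:, None]
        if m.ndim != 2:
            raise ValueError("nuisance matrix must be 2D (t x q)")
        zero = np.all(m == 0, axis=0)
        if zero.any():
            raise ValueError(f"nuisance columns identically zero: {np.nonzero(zero)[0].tolist()}")
        self.matrix = m
        self.names = names or [f"confound_{i}" for i in range(m.shape[1])]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_text(cls, path) -> "NuisanceSet":
        """Read a whitespace-delimited matrix, one row per time point
        (the common motion-parameter file layout)."""
        return cls(np.loadtxt(path, ndmin=2))


def _poly_design(t: int, order: int) -> np.ndarray:
    # orthonormal polynomial basis over the time index, for numerical sanity
    x = np.linspace(-1.0, 1.0, t)
    cols = [x ** p for p in range(order + 1)]
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def detrend_poly(bold: Bold4D, order: int = 2) -> Bold4D:
    """Remove a per-voxel polynomial trend (default linear + quadratic).

    The residual is the least-squares projection away from the polynomial
    basis, so it has zero sample correlation with every basis vector; the
    temporal mean is removed along with the order-0 term.
    """
    if order not in (1, 2):
        raise ValueError("detrend order must be 1 or 2")
    t = bold.n_timepoints
    if t <= order + 1:
        raise ValueError(f"need more than {order + 1} timepoints to fit order-{order} trend")
    q = _poly_design(t, order)
    flat = bold.data.reshape(-1, t)
    resid = flat - (flat @ q) @ q.T
    return bold.with_data(resid.reshape(bold.data.shape))


def regress_nuisance(bold: Bold4D, nuisance: NuisanceSet) -> Bold4D:
    """Per-voxel OLS residual after regressing out all confound columns.

    An intercept is always included in the design.  The output is orthogonal
    to every confound column.
    """
    t = bold.n_timepoints
    if nuisance.n_timepoints != t:
        raise ValueError(
            f"nuisance rows ({nuisance.n_timepoints}) != timepoints ({t})"
        )
    design = np.column_stack([np.ones(t), nuisance.matrix])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by comparing rank with each column removed
        bad = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(nuisance.names[j - 1])
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    q, _ = np.linalg.qr(design)
    flat = bold.data.reshape(-1, t)
    resid = flat - (flat @ q) @ q.T
    return bold.with_data(resid.reshape(bold.data.shape))


def bandpass(bold: Bold4D, low_hz: float = 0.008, high_hz: float = 0.1) -> Bold4D:
    """Temporal band-pass by hard FFT-domain masking.

    Frequency bins with low_hz <= f <= high_hz are kept exactly; everything
    else (including DC when low_hz > 0) is zeroed.
    """
    t = bold.n_timepoints
    nyquist = 1.0 / (2.0 * bold.repetition_time_s)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    freqs = np.fft.rfftfreq(t, d=bold.repetition_time_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    flat = bold.data.reshape(-1, t)
    spec = np.fft.rfft(flat, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=1)
    return bold.with_data(out.reshape(bold.data.shape))


def smooth_gaussian(volume: np.ndarray, sigma_mm: float, affine: np.ndarray) -> np.ndarray:
    """3D Gaussian smoothing of a 3D volume or each frame of a 4D volume.

    ``sigma_mm`` is converted to voxel units through the affine; sheared
    affines are unsupported.  Reflect boundary handling preserves the total
    sum of each frame.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be nonnegative")
    lin = np.asarray(affine, dtype=float)[:3, :3]
    offdiag = lin - np.diag(np.diag(lin))
    if np.abs(offdiag).max() > 1e-8 * max(1.0, np.abs(lin).max()):
        raise ValueError("sheared/oblique affines are unsupported for smoothing")
    voxel_sizes = np.abs(np.diag(lin))
    sigma_vox = sigma_mm / voxel_sizes
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim == 3:
        return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="reflect")
    if vol.ndim == 4:
        out = np.empty_like(vol)
        for f in range(vol.shape[3]):
            out[..., f] = ndimage.gaussian_filter(vol[..., f], sigma=sigma_vox, mode="reflect")
        return out
    raise ValueError("volume must be 3D or 4D")


def smooth_bold(bold: Bold4D, sigma_mm: float) -> Bold4D:
    return bold.with_data(smooth_gaussian(bold.data, sigma_mm, bold.affine))


def intensity_normalize(bold: Bold4D, target: float = GRAND_MEAN) -> Bold4D:
    """Scale the 4D global mean to ``target`` (grand-mean scaling).

    Relative voxel ratios are unchanged; applying twice equals applying once.
    """
    mean = float(bold.data.mean())
    if mean == 0.0:
        raise ValueError("global mean is zero; cannot intensity-normalize")
    return bold.with_data(bold.data * (target / mean))


def drop_initial_frames(bold: Bold4D, n: int) -> Bold4D:
    """Discard the first ``n`` frames (scanner equilibration transient)."""
    if n < 0 or n >= bold.n_timepoints:
        raise ValueError("invalid number of frames to drop")
    return bold.with_data(bold.data[..., n:])


def preprocess_bold(
    bold: Bold4D,
    nuisance: NuisanceSet | None = None,
    detrend_order: int = 2,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    sigma_mm: float = 3.0,
    drop_frames: int = 0,
    normalize: bool = True,
) -> Bold4D:
    """Full cleaning chain.

    Intensity normalization runs first, on the raw (positive-mean) data:
    detrending removes the temporal mean, after which grand-mean scaling
    would be ill-defined.  Correlation-based downstream analyses are
    invariant to this ordering.
    """
    out = bold
    if drop_frames:
        out = drop_initial_frames(out, drop_frames)
    if normalize:
        out = intensity_normalize(out)
    out = detrend_poly(out, detrend_order)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    out = bandpass(out, low_hz, high_hz)
    if sigma_mm > 0:
        out = smooth_bold(out, sigma_mm)
    return out
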