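"""Synthetic multi-subject BOLD data with planted parcel and network structure.

The generator emulates the data layout assumed by a connectivity-based
parcellation study: a seed region composed of C contiguous anatomical
subdivisions, each subdivision's voxels sharing a latent time series that is
also injected into subdivision-specific "target" regions elsewhere in the
brain, plus a set of targets shared by all subdivisions, with additive noise.

Signal model, per subject and parcel ``c`` with latent unit-variance series
``s_c``::

    voxel in parcel c or target_networks[c]:  sqrt(rho)*s_c + sqrt(1-rho)*eps_v
    voxel in shared_targets:                  sqrt(rho)*u   + sqrt(1-rho)*eps_v,
                                              u = sum_c s_c / sqrt(C)
    any other brain voxel:                    noise_sd * eps_v

so the expected Pearson correlation between two voxels sharing latent ``c``
is ``rho``.  All series (latents and noise) are band-limited Gaussian
processes confined to the analysis passband, so the preprocessing band-pass
filter passes the planted structure unchanged; a constant baseline offset is
added so intensity normalization has a nonzero mean to work with.

Each subject draws its latents and noise from an independent RNG stream
derived deterministically from the master seed, so generation is
reproducible and independent of subject order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import Bold4D, mask_coordinates

BASELINE = 1000.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions: 10 subjects on a
    24 x 24 x 16 grid of 2 mm voxels, T = 300 frames at TR = 2 s, four
    planted parcels of 27 voxels each, within-network correlation 0.5.
    """

    n_subjects: int = 10
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_timepoints: int = 300
    repetition_time_s: float = 2.0
    seed_parcels: list[tuple[str, np.ndarray]] = field(default_factory=list)
    target_networks: dict[str, np.ndarray] = field(default_factory=dict)
    shared_targets: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    within_network_corr: float = 0.5
    subject_signal_jitter: float = 0.0
    noise_sd: float = 1.0
    low_hz: float = 0.008
    high_hz: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.seed_parcels:
            self._fill_default_geometry()
        self.validate()

    def _fill_default_geometry(self) -> None:
        """Four 3x3x3 seed parcels in the left half of the grid, four
        subdivision-specific target blocks and one shared-target block in a
        posterior band well away from the seed and its mirror image."""

        def block(x0, y0, z0, w=3):
            xs, ys, zs = np.meshgrid(
                np.arange(x0, x0 + w), np.arange(y0, y0 + w), np.arange(z0, z0 + w),
                indexing="ij",
            )
            return np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]).astype(np.int64)

        self.seed_parcels = [
            ("AON", block(2, 4, 4)),
            ("TUB", block(2, 10, 4)),
            ("PirF", block(6, 4, 8)),
            ("PirT", block(6, 10, 8)),
        ]
        self.target_networks = {
            "AON": block(2, 18, 4),
            "TUB": block(6, 18, 8),
            "PirF": block(14, 18, 4),
            "PirT": block(18, 18, 8),
        }
        self.shared_targets = block(10, 18, 12)

    def validate(self) -> None:
        nx, ny, nz = self.grid_dims
        if self.n_subjects < 1 or self.n_timepoints < 2:
            raise ValueError("need at least 1 subject and 2 timepoints")
        if not (0 <= self.within_network_corr < 1):
            raise ValueError("within_network_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        named = [(f"seed_parcels[{lab}]", c) for lab, c in self.seed_parcels]
        named += [(f"target_networks[{lab}]", c) for lab, c in self.target_networks.items()]
        named += [("shared_targets", self.shared_targets)]
        for name, coords in named:
            coords = np.asarray(coords)
            if coords.size and (
                coords.min() < 0
                or np.any(coords >= np.array([nx, ny, nz])[None, :])
            ):
                raise ValueError(f"{name} has coordinates outside grid {self.grid_dims}")
        for i in range(len(named)):
            for j in range(i + 1, len(named)):
                a = {tuple(c) for c in np.asarray(named[i][1])}
                b = {tuple(c) for c in np.asarray(named[j][1])}
                if a & b:
                    raise ValueError(
                        f"coordinate sets overlap: {named[i][0]} and {named[j][0]}"
                    )

    @property
    def parcel_names(self) -> list[str]:
        return [lab for lab, _ in self.seed_parcels]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def to_json(self) -> str:
        d = {
            "n_subjects": self.n_subjects,
            "grid_dims": list(self.grid_dims),
            "voxel_size_mm": list(self.voxel_size_mm),
            "n_timepoints": self.n_timepoints,
            "repetition_time_s": self.repetition_time_s,
            "seed_parcels": {lab: np.asarray(c).tolist() for lab, c in self.seed_parcels},
            "target_networks": {lab: np.asarray(c).tolist() for lab, c in self.target_networks.items()},
            "shared_targets": np.asarray(self.shared_targets).tolist(),
            "within_network_corr": self.within_network_corr,
            "subject_signal_jitter": self.subject_signal_jitter,
            "noise_sd": self.noise_sd,
            "low_hz": self.low_hz,
            "high_hz": self.high_hz,
            "rng_seed": self.rng_seed,
        }
        return json.dumps(d, indent=1)


@dataclass
class SyntheticDataset:
    """Generated volumes plus every piece of planted ground truth."""

    spec: SyntheticSpec
    bolds: list[Bold4D]
    brain_mask: np.ndarray
    seed_mask: np.ndarray
    anat_labels: np.ndarray          # int volume, 1..C exactly on the seed ROI
    truth_labels: np.ndarray         # ground-truth parcel labels, == anat here
    target_maps: dict[str, np.ndarray]
    shared_mask: np.ndarray
    latents: list[dict[str, np.ndarray]]   # per subject: parcel label -> series
    mix_weights: list[float] = field(default_factory=list)  # per-subject sqrt(rho_s)
    seed_mask_mirrored: np.ndarray | None = None
    anat_labels_mirrored: np.ndarray | None = None
    mirror_axis: int | None = None


def bandlimited_series(rng: np.random.Generator, n: int, t: int, tr: float,
                       low_hz: float, high_hz: float) -> np.ndarray:
    """(n, t) independent unit-variance Gaussian series confined to the band.

    White noise is FFT-masked to [low_hz, high_hz] and each row re-standardized
    to zero mean / unit sample variance.
    """
    white = rng.standard_normal((n, t))
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValueError("passband contains no FFT bins at this T and TR")
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    return out / sd


def _subject_rng(master_seed: int, subject: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, subject, stream]))


def _mix_weight(rho: float, jitter: float, rng: np.random.Generator) -> float:
    """Subject-level mixing weight sqrt(rho_s), rho_s jittered around rho."""
    if jitter == 0.0:
        return float(np.sqrt(rho))
    rho_s = float(np.clip(rho + jitter * rng.standard_normal(), 0.0, 0.95))
    return float(np.sqrt(rho_s))


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Simulate all subjects of the study described by ``spec``.

    Deterministic given ``spec.rng_seed``; each subject owns an independent
    RNG stream derived from the master seed.
    """
    spec.validate()
    nx, ny, nz = spec.grid_dims
    t = spec.n_timepoints
    brain_mask = np.ones(spec.grid_dims, dtype=bool)

    seed_mask = np.zeros(spec.grid_dims, dtype=bool)
    anat = np.zeros(spec.grid_dims, dtype=np.int32)
    for ci, (lab, coords) in enumerate(spec.seed_parcels, start=1):
        c = np.asarray(coords)
        seed_mask[c[:, 0], c[:, 1], c[:, 2]] = True
        anat[c[:, 0], c[:, 1], c[:, 2]] = ci
    target_maps = {}
    for lab, coords in spec.target_networks.items():
        m = np.zeros(spec.grid_dims, dtype=bool)
        c = np.asarray(coords)
        m[c[:, 0], c[:, 1], c[:, 2]] = True
        target_maps[lab] = m
    shared_mask = np.zeros(spec.grid_dims, dtype=bool)
    sc = np.asarray(spec.shared_targets)
    if sc.size:
        shared_mask[sc[:, 0], sc[:, 1], sc[:, 2]] = True

    names = spec.parcel_names
    n_parcels = len(names)
    bolds, latents, mix_weights = [], [], []
    for s in range(spec.n_subjects):
        rng = _subject_rng(spec.rng_seed, s)
        lat = bandlimited_series(rng, n_parcels, t, spec.repetition_time_s,
                                 spec.low_hz, spec.high_hz)
        lat_by_name = {nm: lat[i] for i, nm in enumerate(names)}
        a = _mix_weight(spec.within_network_corr, spec.subject_signal_jitter, rng)
        b = float(np.sqrt(1.0 - a * a))

        data = spec.noise_sd * bandlimited_series(
            rng, nx * ny * nz, t, spec.repetition_time_s, spec.low_hz, spec.high_hz
        ).reshape(nx, ny, nz, t)

        for i, (lab, coords) in enumerate(spec.seed_parcels):
            c = np.asarray(coords)
            eps = bandlimited_series(rng, len(c), t, spec.repetition_time_s,
                                     spec.low_hz, spec.high_hz)
            data[c[:, 0], c[:, 1], c[:, 2], :] = a * lat[i] + b * eps
        for lab, coords in spec.target_networks.items():
            c = np.asarray(coords)
            eps = bandlimited_series(rng, len(c), t, spec.repetition_time_s,
                                     spec.low_hz, spec.high_hz)
            data[c[:, 0], c[:, 1], c[:, 2], :] = a * lat_by_name[lab] + b * eps
        if sc.size:
            u = lat.sum(axis=0) / np.sqrt(n_parcels)
            eps = bandlimited_series(rng, len(sc), t, spec.repetition_time_s,
                                     spec.low_hz, spec.high_hz)
            data[sc[:, 0], sc[:, 1], sc[:, 2], :] = a * u + b * eps

        data += BASELINE
        bolds.append(Bold4D(data, spec.affine, spec.repetition_time_s))
        latents.append(lat_by_name)
        mix_weights.append(a)

    return SyntheticDataset(
        spec=spec, bolds=bolds, brain_mask=brain_mask, seed_mask=seed_mask,
        anat_labels=anat, truth_labels=anat.copy(), target_maps=target_maps,
        shared_mask=shared_mask, latents=latents, mix_weights=mix_weights,
    )


def scaled_spec(grid_dims: tuple[int, int, int] = (16, 16, 12),
                parcel_width: int = 2, **kwargs) -> SyntheticSpec:
    """A spec with the default layout scaled proportionally onto a smaller grid.

    Seed parcels sit in the left half of the x axis, subdivision-specific and
    shared targets in a posterior y band, all as ``parcel_width``-cubes at
    positions proportional to the default 24 x 24 x 16 layout.  Validation
    rejects any grid too small to keep the blocks disjoint.
    """
    nx, ny, nz = grid_dims

    def block(fx, fy, fz):
        x0 = max(1, int(fx * nx))
        y0 = max(1, int(fy * ny))
        z0 = max(0, int(fz * nz))
        w = parcel_width
        xs, ys, zs = np.meshgrid(np.arange(x0, x0 + w), np.arange(y0, y0 + w),
                                 np.arange(z0, z0 + w), indexing="ij")
        return np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]).astype(np.int64)

    seed_parcels = [
        ("AON", block(2 / 24, 4 / 24, 4 / 16)),
        ("TUB", block(2 / 24, 10 / 24, 4 / 16)),
        ("PirF", block(6 / 24, 4 / 24, 8 / 16)),
        ("PirT", block(6 / 24, 10 / 24, 8 / 16)),
    ]
    target_networks = {
        "AON": block(2 / 24, 18 / 24, 4 / 16),
        "TUB": block(6 / 24, 18 / 24, 8 / 16),
        "PirF": block(14 / 24, 18 / 24, 4 / 16),
        "PirT": block(18 / 24, 18 / 24, 8 / 16),
    }
    shared = block(10 / 24, 18 / 24, 12 / 16)
    return SyntheticSpec(grid_dims=grid_dims, seed_parcels=seed_parcels,
                         target_networks=target_networks, shared_targets=shared,
                         **kwargs)


def _mirror_coords(coords: np.ndarray, axis: int, n: int) -> np.ndarray:
    out = np.asarray(coords).copy()
    out[:, axis] = n - 1 - out[:, axis]
    return out


def mirror_hemispheres(dataset: SyntheticDataset, axis: int = 0) -> SyntheticDataset:
    """Plant a mirror-image seed ROI carrying the SAME latent signals.

    The seed ROI must lie strictly on one side of the grid's mid-plane along
    ``axis``.  Each mirrored seed voxel receives the latent series of its
    source voxel mixed with fresh independent noise, so the left and right
    seed connectivity maps are exchangeable voxel-by-voxel — the correct null
    for the lateralization-index group test.
    """
    spec = dataset.spec
    n = spec.grid_dims[axis]
    coords = mask_coordinates(dataset.seed_mask)
    half = n / 2.0
    lo, hi = coords[:, axis].min(), coords[:, axis].max()
    if not (hi < half or lo >= half):
        raise ValueError(f"seed ROI straddles the mirror plane along axis {axis}")

    mirrored = _mirror_coords(coords, axis, n)
    seed_m = np.zeros(spec.grid_dims, dtype=bool)
    seed_m[mirrored[:, 0], mirrored[:, 1], mirrored[:, 2]] = True
    if (seed_m & dataset.seed_mask).any():
        raise ValueError("mirrored seed ROI overlaps the original")
    anat_m = np.zeros_like(dataset.anat_labels)
    anat_m[mirrored[:, 0], mirrored[:, 1], mirrored[:, 2]] = dataset.anat_labels[
        coords[:, 0], coords[:, 1], coords[:, 2]
    ]

    names = spec.parcel_names
    new_bolds = []
    for s, bold in enumerate(dataset.bolds):
        rng = _subject_rng(spec.rng_seed, s, stream=1)
        # reuse the subject's mixing weight so both hemispheres share rho_s
        a = dataset.mix_weights[s] if dataset.mix_weights else float(
            np.sqrt(spec.within_network_corr))
        b = float(np.sqrt(1.0 - a * a))
        data = bold.data.copy()
        for ci, nm in enumerate(names, start=1):
            sel = mirrored[dataset.anat_labels[coords[:, 0], coords[:, 1], coords[:, 2]] == ci]
            if not len(sel):
                continue
            eps = bandlimited_series(rng, len(sel), spec.n_timepoints,
                                     spec.repetition_time_s, spec.low_hz, spec.high_hz)
            data[sel[:, 0], sel[:, 1], sel[:, 2], :] = (
                a * dataset.latents[s][nm] + b * eps + BASELINE
            )
        new_bolds.append(bold.with_data(data))

    return SyntheticDataset(
        spec=spec, bolds=new_bolds, brain_mask=dataset.brain_mask,
        seed_mask=dataset.seed_mask, anat_labels=dataset.anat_labels,
        truth_labels=dataset.truth_labels, target_maps=dataset.target_maps,
        shared_mask=dataset.shared_mask, latents=dataset.latents,
        mix_weights=dataset.mix_weights,
        seed_mask_mirrored=seed_m, anat_labels_mirrored=anat_m, mirror_axis=axis,
    )


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write NIfTI volumes and a JSON sidecar recording all parameters."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = dataset.spec.affine
    for s, bold in enumerate(dataset.bolds):
        _io.write_nifti(bold.data, aff, out / f"sub-{s:02d}_bold.nii")
    _io.write_nifti(dataset.brain_mask.astype(np.uint8), aff, out / "brain_mask.nii")
    _io.write_nifti(dataset.seed_mask.astype(np.uint8), aff, out / "seed_mask.nii")
    _io.write_nifti(dataset.anat_labels, aff, out / "anat_labels.nii")
    (out / "spec.json").write_text(dataset.spec.to_json())
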