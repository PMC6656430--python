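"""NIfTI and table input/output, plus the pipeline configuration object.

All voxel coordinates in outputs are 0-based; every table and sidecar that
reports coordinates states this convention in its header.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


def read_nifti(path: str | Path, expect_ndim: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine).

    Integer on-disk dtypes come back as integers (label images stay labels);
    floating volumes come back float64.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise ValueError(f"{path}: expected {expect_ndim}D data, found {data.ndim}D")
    return data, img.affine


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving integer dtypes for label images."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))


def write_table(df, path: str | Path) -> None:
    """Tab-delimited table with header; coordinates (if any) are 0-based."""
    df.to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Everything needed to (re)run the full analysis.

    ``profile`` selects parameter scale: "paper" uses 10,000 permutations
    everywhere; "desk" uses 1,000-permutation group inference sized for
    interactive runs on a laptop.
    """

    output_dir: str = "olfparc_out"
    bold_paths: list[str] = field(default_factory=list)
    brain_mask_path: str = ""
    seed_mask_path: str = ""
    anat_labels_path: str = ""
    nuisance_paths: list[str] = field(default_factory=list)
    atlas_path: str = ""
    simulate: bool = True

    detrend_order: int = 2
    low_hz: float = 0.008
    high_hz: float = 0.1
    sigma_mm: float = 3.0
    drop_frames: int = 0

    k: int = 4
    k_sweep: list[int] = field(default_factory=list)
    n_init: int = 10
    n_perm_parcel: int = 10000
    n_perm_group: int = 1000
    alpha: float = 0.001
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_steps: int = 100
    tfce_neighbourhood: int = 26
    li_eps: float = 1e-6
    rng_seed: int = 0
    profile: str = "desk"

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "desk"):
            raise ValueError("profile must be 'paper' or 'desk'")
        if self.profile == "paper":
            self.n_perm_group = max(self.n_perm_group, 10000)
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("invalid passband")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())
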