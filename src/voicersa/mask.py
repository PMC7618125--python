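"""Voxel masks and item-pattern datasets with NIfTI I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VoxelMask", "PatternDataset"]


@dataclass
class VoxelMask:
    """3-D boolean voxel grid with an optional affine (mm geometry)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("mask must be 3-D")
        if d.size == 0 or min(d.shape) < 1:
            raise ValueError("mask grid dimensions must be positive")
        self.data = d.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if not self.data.any():
            raise ValueError("mask contains no voxels")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def coords(self) -> np.ndarray:
        """0-based integer voxel coordinates of in-mask voxels, C-order."""
        return np.argwhere(self.data)

    def volume_from_values(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-mask-voxel values into a 3-D volume (NaN background)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError("values length must equal number of mask voxels")
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.data] = values
        return vol

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, img.affine)


@dataclass
class PatternDataset:
    """Items x voxels response patterns (e.g. T statistics) over a mask.

    Rows follow ``labels``; columns follow ``mask.coords()`` order when a
    mask is attached.
    """

    patterns: np.ndarray
    labels: list
    mask: VoxelMask | None = None

    def __post_init__(self):
        p = np.asarray(self.patterns, dtype=float)
        if p.ndim != 2:
            raise ValueError("patterns must be 2-D (items x voxels)")
        self.patterns = p
        self.labels = [(str(i), int(c)) for i, c in self.labels]
        if len(self.labels) != p.shape[0]:
            raise ValueError("label count does not match pattern rows")
        if self.mask is not None and self.mask.n_voxels != p.shape[1]:
            raise ValueError("pattern columns do not match mask voxel count")

    @property
    def n_items(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    # -- NIfTI 4-D + CSV label sidecar ---------------------------------------
    def to_nifti(self, path, labels_path=None) -> None:
        if self.mask is None:
            raise ValueError("a mask is required to write patterns as NIfTI")
        vol = np.full(self.mask.shape + (self.n_items,), np.nan, dtype=np.float64)
        for k in range(self.n_items):
            vol[..., k][self.mask.data] = self.patterns[k]
        nib.save(nib.Nifti1Image(vol, self.mask.affine), str(path))
        if labels_path is not None:
            pd.DataFrame(self.labels, columns=["identity", "clip"]).to_csv(
                labels_path, index=False
            )

    @classmethod
    def from_nifti(cls, path, labels_path, mask: VoxelMask) -> "PatternDataset":
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError("expected a 4-D pattern image (item on 4th axis)")
        pats = np.stack([vol[..., k][mask.data] for k in range(vol.shape[3])])
        lab = pd.read_csv(labels_path)
        labels = list(zip(lab["identity"], lab["clip"].astype(int)))
        return cls(pats, labels, mask)
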