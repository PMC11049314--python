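"""Volume containers and NIfTI round-trip helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .params import ParameterError

__all__ = ["TiSeries", "LabelVolume", "CLASS_NAMES", "save_nifti", "load_nifti"]

# canonical label codes: background is 0
CLASS_NAMES = ("WM", "GM", "CSF", "T2L-1", "T2L-2", "CEL", "NEC")


@dataclass
class TiSeries:
    """A 4-D multi-TI magnitude series: (x, y, z, inversion time).

    ``ti_ms`` holds the frame-center inversion times of the reconstructed
    frames (default 20 per inversion cycle).
    """

    volume: np.ndarray
    voxel_size_mm: tuple
    ti_ms: np.ndarray

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        self.ti_ms = np.asarray(self.ti_ms, dtype=float)
        if self.volume.ndim != 4:
            raise ParameterError("TiSeries volume must be 4-D (x, y, z, TI)")
        if self.volume.shape[3] != len(self.ti_ms):
            raise ParameterError(
                f"4th dimension ({self.volume.shape[3]}) must match number of "
                f"inversion times ({len(self.ti_ms)})"
            )
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ParameterError("voxel_size_mm must be 3 positive lengths")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def n_frames(self) -> int:
        return self.volume.shape[3]

    @property
    def shape(self) -> tuple:
        return self.volume.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        v = self.voxel_size_mm
        return v[0] * v[1] * v[2]


@dataclass
class LabelVolume:
    """Integer-coded segmentation; code 0 is background, code i is
    ``class_names[i-1]``."""

    labels: np.ndarray
    class_names: tuple = CLASS_NAMES
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ParameterError("labels must be 3-D")
        if self.labels.min() < 0 or self.labels.max() > len(self.class_names):
            raise ParameterError("label codes must lie in [0, n_classes]")
        self.class_names = tuple(self.class_names)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == (self.class_names.index(name) + 1)

    @property
    def voxel_volume_mm3(self) -> float:
        v = self.voxel_size_mm
        return v[0] * v[1] * v[2]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def save_nifti(data: np.ndarray, voxel_size_mm, path, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm)), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vox
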