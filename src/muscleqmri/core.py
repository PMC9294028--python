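"""Core in-memory containers for the imaging pipeline.

Volumes are plain numpy arrays plus voxel spacing in millimetres; NIfTI
round-trips go through nibabel with a diagonal affine built from the spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Tissue",
    "ImageVolume",
    "TissueLabelMap",
    "MultiEchoSeries",
    "ConfigurationError",
    "DegenerateInputError",
]


class ConfigurationError(ValueError):
    """Raised when generation / analysis parameters are inconsistent."""


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. constant volume)."""


class Tissue:
    """Integer label palette shared by the generator and the segmenter."""

    BACKGROUND = 0
    BONE = 1
    SUBCUTANEOUS_FAT = 2
    LEAN_MUSCLE = 3
    INTERMUSCULAR_FAT = 4
    PHANTOM = 5

    NAMES = {
        BACKGROUND: "background",
        BONE: "bone",
        SUBCUTANEOUS_FAT: "subcutaneous_fat",
        LEAN_MUSCLE: "lean_muscle",
        INTERMUSCULAR_FAT: "intermuscular_fat",
        PHANTOM: "phantom",
    }


def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A single-contrast 3-D scalar grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), _affine_from_spacing(self.spacing))
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing)


@dataclass
class TissueLabelMap:
    """Per-voxel categorical tissue map using the :class:`Tissue` palette."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.ndim != 3:
            raise ConfigurationError(f"expected a 3-D label map, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask(self, *tissues: int) -> np.ndarray:
        return np.isin(self.data, tissues)

    @property
    def bundle_mask(self) -> np.ndarray:
        """Muscle bundle = lean muscle plus inter/intramuscular fat."""
        return self.mask(Tissue.LEAN_MUSCLE, Tissue.INTERMUSCULAR_FAT)

    def count(self, tissue: int) -> int:
        return int(np.count_nonzero(self.data == tissue))

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), _affine_from_spacing(self.spacing))
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "TissueLabelMap":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.int16), spacing)


@dataclass
class MultiEchoSeries:
    """Multi-echo spin-echo series: one volume per echo time (ms)."""

    echo_times_ms: tuple[float, ...]
    data: np.ndarray = field(repr=False)  # (nx, ny, nz, n_echoes)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.echo_times_ms = tuple(float(t) for t in self.echo_times_ms)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != len(self.echo_times_ms):
            raise ConfigurationError(
                f"series must be (nx, ny, nz, n_echoes={len(self.echo_times_ms)}); got {self.data.shape}"
            )
        if len(self.echo_times_ms) < 2 or np.any(np.diff(self.echo_times_ms) <= 0):
            raise ConfigurationError("echo times must be strictly increasing")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def echo_volume(self, i: int) -> ImageVolume:
        return ImageVolume(self.data[..., i], self.spacing)

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), _affine_from_spacing(self.spacing))
        img.header["pixdim"][4] = 1.0
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, echo_times_ms: Sequence[float]) -> "MultiEchoSeries":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(tuple(echo_times_ms), np.asarray(img.dataobj, dtype=np.float64), spacing)
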