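"""Core in-memory containers for reconstructed volumes and sub-volumes.

Axis convention throughout the package: arrays are indexed ``(z, y, x)`` with
0-based voxel indices, ``z`` is the tendon (fiber) axis, and the voxel size is
isotropic and carried in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ValidationError

ContentLabel = Literal["fibers", "fat_cells"]


@dataclass
class VolumeStack:
    """A 3D gray-scale volume with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Gray values as floats. Gray levels are abstract; any integer export
        windowing is handled at I/O time, not here.
    voxel_size : float
        Isotropic voxel edge length in µm.
    metadata : dict
        Free-form provenance (generator spec, applied rotations, ...).
    """

    data: np.ndarray
    voxel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3D (z, y, x); got ndim={self.data.ndim}"
            )
        if not self.voxel_size > 0:
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SubVolume:
    """An axis-aligned sub-volume cut from a parent :class:`VolumeStack`.

    ``content_label`` governs which quality metrics are legal: spatial
    resolution, FMCR and UTS are defined on fiber sub-volumes, GSE on
    fat-cell sub-volumes.
    """

    data: np.ndarray
    voxel_size: float
    content_label: ContentLabel
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("sub-volume must be 3D (z, y, x)")
        if not self.voxel_size > 0:
            raise ValidationError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.content_label not in ("fibers", "fat_cells"):
            raise ValidationError(
                f"content_label must be 'fibers' or 'fat_cells', got "
                f"{self.content_label!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]
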