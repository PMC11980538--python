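"""In-memory image container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelImage:
    """A 3D or 4D scalar intensity lattice with voxel spacing.

    Intensities are magnitude-reconstructed MR data: finite and non-negative.
    The 4th axis, when present, is time (functional) or diffusion direction;
    ``bvalues`` aligns with it for diffusion acquisitions.
    """

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bvalues: list[float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got {arr.ndim}D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("intensities must be non-negative (magnitude data)")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.bvalues is not None:
            if arr.ndim != 4:
                raise ValueError("bvalues given for a 3D image")
            if len(self.bvalues) != arr.shape[3]:
                raise ValueError(
                    f"{len(self.bvalues)} b-values for {arr.shape[3]} volumes"
                )
            if any(b < 0 for b in self.bvalues):
                raise ValueError("b-values must be non-negative")
        self.intensities = arr

    @property
    def dims(self) -> tuple[int, ...]:
        return self.intensities.shape

    @property
    def is_4d(self) -> bool:
        return self.intensities.ndim == 4

    @property
    def n_volumes(self) -> int:
        return self.intensities.shape[3] if self.is_4d else 1

    def volume(self, index: int) -> "VoxelImage":
        """Extract one 3D volume from a 4D series."""
        if not self.is_4d:
            raise ValueError("volume() requires a 4D image")
        return VoxelImage(self.intensities[..., index], self.voxel_size_mm)

    def time_average(self) -> np.ndarray:
        """3D mean over the 4th axis (identity view for 3D input)."""
        return self.intensities.mean(axis=3) if self.is_4d else self.intensities
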