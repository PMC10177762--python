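"""Binary 3D volume container used by the morphometry operations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BinaryVolume:
    """A 3D boolean lattice with isotropic-or-not voxel spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if self.grid.dtype != bool:
            self.grid = self.grid.astype(bool)
        if max(self.grid.shape) < 2:
            raise ValueError("at least one dimension must be >= 2")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive edge lengths")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryVolume):
            return NotImplemented
        return (
            self.grid.shape == other.grid.shape
            and bool(np.array_equal(self.grid, other.grid))
            and self.spacing == other.spacing
        )
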