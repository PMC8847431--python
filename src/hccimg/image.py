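"""Reconstructed 3D image container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGrid


@dataclass
class Image3D:
    """Voxelized image values (lambda) on a world-frame grid."""

    values: np.ndarray  # shape grid.shape
    grid: VoxelGrid
    n_iter: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("image shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("image values must be non-negative")
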