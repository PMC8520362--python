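"""Regular 3D voxel grid with physical-space metadata.

Conventions (fixed package-wide): voxel-center sampling, 0-based indices,
``data`` indexed ``[i, j, k]`` along (x, y, z), and the center of voxel
(i, j, k) at ``origin + (i, j, k) * spacing`` in mm.  Missing voxels carry
NaN in ``data`` plus an explicit boolean mask so the round trip through
float files is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError


@dataclass
class VoxelGrid:
    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).ravel()
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        if self.data.ndim != 3:
            raise DomainError(f"data must be 3D, got ndim={self.data.ndim}")
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise DomainError("spacing and origin must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise DomainError(f"spacing must be positive, got {self.spacing}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.data)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.data.shape:
                raise DomainError("missing_mask shape must match data shape")
        if not np.all(np.isfinite(self.data[~self.missing_mask])):
            raise DomainError("data must be finite outside the missing mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, C-order raveled (N, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def index_to_world(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    @classmethod
    def empty(cls, shape, spacing, origin) -> "VoxelGrid":
        data = np.full(tuple(int(s) for s in shape), np.nan)
        return cls(data=data, spacing=spacing, origin=origin)

    @classmethod
    def from_box(cls, lower, upper, spacing) -> "VoxelGrid":
        """Grid of NaN voxels whose centers tile the box [lower, upper].

        The first voxel center sits at ``lower``; the last does not exceed
        ``upper``.
        """
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,)).copy()
        if np.any(upper < lower):
            raise DomainError("upper must be >= lower")
        shape = np.floor((upper - lower) / spacing + 1e-9).astype(int) + 1
        return cls.empty(shape, spacing, lower)
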