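"""Voxel grid geometry shared by images, attenuation maps and masks."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid3D:
    """A regular voxel grid with a grid-center world origin.

    Axes are (x, y, z); rotation for projection happens in the (x, y)
    plane and z is the scanner axis. World coordinates are in mm,
    measured from the center of the grid (``origin`` shifts that center).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (mm)."""
        n = self.shape[axis]
        d = self.spacing[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d + self.origin[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (X, Y, Z) world coordinates of all voxel centers."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def extent(self) -> tuple[float, float, float]:
        """Physical half-extent of the grid along each axis (mm)."""
        return tuple(n * s / 2.0 for n, s in zip(self.shape, self.spacing))


@dataclass
class ActivityImage:
    """Voxelized emission concentration (arbitrary units ~ Bq/mL)."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("activity values must be nonnegative")

    @property
    def total_activity(self) -> float:
        """Total activity: sum of concentration times voxel volume."""
        return float(self.values.sum() * self.grid.voxel_volume)


@dataclass
class MuMap:
    """Linear attenuation map (mm^-1) at the primary photon energy.

    ``labels`` marks each voxel as air (0) or water (1); the transport
    engine only distinguishes those two materials.
    """

    grid: Grid3D
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("attenuation must be nonnegative")
        if self.labels is None:
            self.labels = (self.values > 0).astype(np.uint8)


@dataclass
class ROI:
    label: str
    mask: np.ndarray
    role: str  # sphere | background | cold
    true_activity: float


@dataclass
class ROISet:
    """Labeled binary masks with known true activity per region."""

    grid: Grid3D
    rois: list[ROI] = field(default_factory=list)

    def add(self, label: str, mask: np.ndarray, role: str, true_activity: float):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        self.rois.append(ROI(label, mask, role, float(true_activity)))

    def __getitem__(self, label: str) -> ROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [r.label for r in self.rois]
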