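"""Voxel-grid containers shared by the dose engine, phantoms and evaluation.

Conventions (used everywhere in this package):

* lengths are millimetres, dose is Gy per unit spot weight;
* the beam travels along +z at gantry angle 0 and the gantry rotates about
  the +y axis, so a cylinder phantom has its axis along y;
* voxel indices are 0-based and world coordinates refer to voxel centres;
* the world origin is the isocentre (phantom centre for the built-in
  phantoms).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phantom", "DoseGrid"]


def _axes(origin: np.ndarray, spacing: np.ndarray, shape: tuple[int, ...]):
    return tuple(
        origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3)
    )


@dataclass
class Phantom:
    """Voxelised relative-stopping-power map with named ROI masks.

    ``rsp`` is the proton stopping power relative to water (water = 1,
    vacuum/air = 0).  ``roi_masks`` holds boolean masks on the same grid;
    the built-in phantoms provide ``target``, ``skin``, ``ring10`` and
    ``body``, with ``body`` a superset of every other mask.
    """

    rsp: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rsp = np.asarray(self.rsp, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.rsp.ndim != 3:
            raise ValueError("rsp map must be 3-D")
        if np.any(self.rsp < 0) or not np.all(np.isfinite(self.rsp)):
            raise ValueError("rsp must be finite and >= 0")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        for name, m in self.roi_masks.items():
            if m.shape != self.rsp.shape:
                raise ValueError(f"mask {name!r} not on the phantom grid")
        body = self.roi_masks.get("body")
        if body is not None:
            for name, m in self.roi_masks.items():
                if name != "body" and np.any(m & ~body):
                    raise ValueError(f"mask {name!r} extends outside body")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.rsp.shape

    @property
    def axes(self):
        """World coordinates of voxel centres along (x, y, z)."""
        return _axes(self.origin, self.spacing, self.rsp.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def empty_dose(self) -> "DoseGrid":
        return DoseGrid(
            values=np.zeros(self.rsp.shape),
            origin=self.origin.copy(),
            spacing=self.spacing.copy(),
        )


@dataclass
class DoseGrid:
    """Absorbed dose per voxel on the same grid layout as a :class:`Phantom`."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < -1e-12):
            raise ValueError("dose values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def axes(self):
        return _axes(self.origin, self.spacing, self.values.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.values.copy(), self.origin.copy(),
                        self.spacing.copy(), dict(self.meta))
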