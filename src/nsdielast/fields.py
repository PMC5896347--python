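"""Grid-sampled field containers shared across the pipeline.

Coordinate convention (used by every module):

* axial = row axis (index 0), increasing with depth, coordinate ``y`` in mm;
* lateral = column axis (index 1), increasing to the right, coordinate ``x`` in mm;
* displacements are in mm, positive down (axial) / right (lateral).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["DisplacementField", "StrainTensorField", "NSDIImage"]


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2D array, got shape {a.shape}")
    return a


@dataclass
class DisplacementField:
    """Axial/lateral displacement components on a regular spatial grid.

    ``state`` distinguishes the ultrasonically *measured* field (the tracker
    output, noisy especially laterally), the *regularized* field produced by
    the incompressibility denoiser, and *ground_truth* fields sampled from a
    finite-element solution.
    """

    u_axial: np.ndarray
    v_lateral: np.ndarray
    grid_spacing_mm: Tuple[float, float]  # (axial, lateral)
    origin_mm: Tuple[float, float] = (0.0, 0.0)  # (axial, lateral) of pixel [0, 0]
    valid_mask: Optional[np.ndarray] = None
    state: str = "measured"
    quality: Optional[np.ndarray] = None  # peak NCC in [-1, 1] where defined

    def __post_init__(self) -> None:
        self.u_axial = _as_2d(self.u_axial)
        self.v_lateral = _as_2d(self.v_lateral)
        if self.u_axial.shape != self.v_lateral.shape:
            raise ValueError("u_axial and v_lateral must share shape")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.u_axial.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.u_axial.shape:
                raise ValueError("valid_mask shape mismatch")
        if self.quality is not None:
            self.quality = _as_2d(self.quality)
            finite = np.isfinite(self.quality)
            if np.any(np.abs(self.quality[finite]) > 1 + 1e-9):
                raise ValueError("quality values must lie in [-1, 1]")
        sy, sx = self.grid_spacing_mm
        if sy <= 0 or sx <= 0:
            raise ValueError("grid spacing must be positive")
        if self.state not in ("measured", "regularized", "ground_truth"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.u_axial.shape

    def axial_coords_mm(self) -> np.ndarray:
        return self.origin_mm[0] + self.grid_spacing_mm[0] * np.arange(self.shape[0])

    def lateral_coords_mm(self) -> np.ndarray:
        return self.origin_mm[1] + self.grid_spacing_mm[1] * np.arange(self.shape[1])

    def with_state(self, state: str) -> "DisplacementField":
        return replace(self, state=state)

    def copy(self) -> "DisplacementField":
        return DisplacementField(
            self.u_axial.copy(),
            self.v_lateral.copy(),
            self.grid_spacing_mm,
            self.origin_mm,
            self.valid_mask.copy(),
            self.state,
            None if self.quality is None else self.quality.copy(),
        )


@dataclass
class StrainTensorField:
    """2D infinitesimal strain tensor on a regular grid.

    ``exx`` is the lateral normal strain, ``eyy`` the axial normal strain and
    ``exy`` the (full, rotation-free) shear strain
    exy = (d u_axial/d lateral + d v_lateral/d axial) / 2.
    """

    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    grid_spacing_mm: Tuple[float, float]
    origin_mm: Tuple[float, float] = (0.0, 0.0)
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.exx = _as_2d(self.exx)
        self.eyy = _as_2d(self.eyy)
        self.exy = _as_2d(self.exy)
        if not (self.exx.shape == self.eyy.shape == self.exy.shape):
            raise ValueError("strain components must share shape")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.exx.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.exx.shape:
                raise ValueError("valid_mask shape mismatch")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.exx.shape

    def axial_coords_mm(self) -> np.ndarray:
        return self.origin_mm[0] + self.grid_spacing_mm[0] * np.arange(self.shape[0])

    def lateral_coords_mm(self) -> np.ndarray:
        return self.origin_mm[1] + self.grid_spacing_mm[1] * np.arange(self.shape[1])


@dataclass
class NSDIImage:
    """Normalized shear deformation indicator image.

    ``values`` = |theta_p| / (pi/4), in [0, 1]; ``theta_p`` is the principal
    angle folded into [-pi/4, pi/4].
    """

    values: np.ndarray
    theta_p: np.ndarray
    grid_spacing_mm: Tuple[float, float]
    origin_mm: Tuple[float, float] = (0.0, 0.0)
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        self.theta_p = _as_2d(self.theta_p)
        if self.values.shape != self.theta_p.shape:
            raise ValueError("values and theta_p must share shape")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        v = self.values[self.valid_mask]
        if v.size and (np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12):
            raise ValueError("NSDI values must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def axial_coords_mm(self) -> np.ndarray:
        return self.origin_mm[0] + self.grid_spacing_mm[0] * np.arange(self.shape[0])

    def lateral_coords_mm(self) -> np.ndarray:
        return self.origin_mm[1] + self.grid_spacing_mm[1] * np.arange(self.shape[1])
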