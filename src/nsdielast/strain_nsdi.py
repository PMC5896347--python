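"""Strain tensor estimation, principal angle and the NSDI image.

The normalized shear deformation indicator (NSDI) measures how strongly the
local deformation is sheared relative to the imaging axes.  From the 2D
strain tensor (lateral normal strain exx, axial normal strain eyy, shear
strain exy) the principal angle

    theta_p = 1/2 * atan2(2 exy, exx - eyy)

is the angle between the lateral axis and the first principal strain
direction.  theta_p is folded to the *nearest* principal axis (subtract
pi/2 when |theta_p| > pi/4), so |theta_p| <= pi/4 identically: with no
shear theta_p = 0, under pure shear (exx = eyy = 0) theta_p = pi/4.  The
indicator is then

    NSDI = |theta_p| / (pi/4)   in [0, 1].

Unlike the axial-shear strain (the lateral derivative of axial displacement
alone), the full shear strain entering theta_p is symmetric in the
displacement gradient, so rigid-body rotation does not contribute.

Spatial derivatives are estimated as slopes of moving least-squares linear
fits over a 1.8 mm window (Savitzky-Golay first derivative), which low-pass
filters the displacement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .fields import DisplacementField, NSDIImage, StrainTensorField

__all__ = [
    "LesionROI",
    "estimate_strains",
    "principal_angle",
    "nsdi",
    "nsdi_from_strain",
    "roi_stats",
    "make_outside_band",
    "size_ratio",
]

QUARTER_PI = np.pi / 4.0


def _check_polygon(contour: np.ndarray, name: str) -> Polygon:
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid or not poly.is_simple:
        raise ValueError(f"{name} must be a simple (non-self-intersecting) polygon")
    return poly


@dataclass
class LesionROI:
    """Lesion contour(s) and the derived inside / equal-area outside masks.

    Contours are (n, 2) vertex arrays with columns (x lateral mm, y axial
    mm); ``contour`` is the lesion boundary drawn on the axial strain
    elastogram, ``bmode_contour`` optionally the boundary on the B-mode
    image.
    """

    contour: np.ndarray
    bmode_contour: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        _check_polygon(self.contour, "contour")
        if self.bmode_contour is not None:
            self.bmode_contour = np.asarray(self.bmode_contour, dtype=float)
            _check_polygon(self.bmode_contour, "bmode_contour")

    def inside_mask(
        self,
        shape: Tuple[int, int],
        grid_spacing_mm: Tuple[float, float],
        origin_mm: Tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        """Rasterize the strain-elastogram contour onto a pixel grid."""
        sy, sx = grid_spacing_mm
        oy, ox = origin_mm
        rc = np.column_stack(
            [(self.contour[:, 1] - oy) / sy, (self.contour[:, 0] - ox) / sx]
        )
        return polygon2mask(shape, rc)

    def outside_band_mask(
        self,
        shape: Tuple[int, int],
        grid_spacing_mm: Tuple[float, float],
        origin_mm: Tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        return make_outside_band(self.inside_mask(shape, grid_spacing_mm, origin_mm))


def estimate_strains(field: DisplacementField, window_mm: float = 1.8) -> StrainTensorField:
    """Estimate (exx, eyy, exy) from a displacement field.

    Each spatial derivative is the slope of a least-squares linear fit over
    a ``window_mm`` moving window along the differentiation axis
    (Savitzky-Golay, polynomial order 1, first derivative). The shear
    strain is exy = (d u_axial/d lateral + d v_lateral/d axial) / 2.
    Border pixels whose window is truncated are masked invalid.
    """
    sy, sx = field.grid_spacing_mm

    def win(spacing: float) -> int:
        w = int(round(window_mm / spacing))
        if w < 3:
            raise ValueError(
                f"strain window {window_mm} mm spans fewer than 3 grid steps of {spacing} mm"
            )
        return w if w % 2 == 1 else w + 1

    w_ax, w_lat = win(sy), win(sx)

    def ddy(a):  # d/d axial (rows)
        return savgol_filter(a, w_ax, polyorder=1, deriv=1, delta=sy, axis=0, mode="interp")

    def ddx(a):  # d/d lateral (cols)
        return savgol_filter(a, w_lat, polyorder=1, deriv=1, delta=sx, axis=1, mode="interp")

    eyy = ddy(field.u_axial)
    exx = ddx(field.v_lateral)
    exy = 0.5 * (ddx(field.u_axial) + ddy(field.v_lateral))

    valid = field.valid_mask.copy()
    hy, hx = w_ax // 2, w_lat // 2
    border = np.zeros_like(valid)
    border[hy:-hy or None, hx:-hx or None] = True
    valid &= border
    return StrainTensorField(
        exx=exx,
        eyy=eyy,
        exy=exy,
        grid_spacing_mm=field.grid_spacing_mm,
        origin_mm=field.origin_mm,
        valid_mask=valid,
    )


def principal_angle(strain: StrainTensorField) -> np.ndarray:
    """Principal angle theta_p per pixel, folded into [-pi/4, pi/4].

    The raw half-angle atan2(2 exy, exx - eyy) / 2 lies in (-pi/2, pi/2];
    when |raw| > pi/4 the *other* principal axis is closer to the lateral
    direction, so pi/2 is subtracted with the raw sign.  Isotropic pixels
    (both atan2 arguments zero) return 0 by convention.
    """
    raw = 0.5 * np.arctan2(2.0 * strain.exy, strain.exx - strain.eyy)
    fold = np.abs(raw) > QUARTER_PI
    theta = np.where(fold, raw - np.sign(raw) * (np.pi / 2.0), raw)
    return theta


def nsdi(
    theta_p: np.ndarray,
    grid_spacing_mm: Tuple[float, float],
    origin_mm: Tuple[float, float] = (0.0, 0.0),
    valid_mask: Optional[np.ndarray] = None,
) -> NSDIImage:
    """Normalize the folded principal angle: NSDI = |theta_p| / (pi/4)."""
    theta_p = np.asarray(theta_p, dtype=float)
    if np.any(np.abs(theta_p[np.isfinite(theta_p)]) > QUARTER_PI * (1 + 1e-12)):
        raise ValueError("theta_p must be folded into [-pi/4, pi/4] before normalization")
    values = np.abs(theta_p) / QUARTER_PI
    return NSDIImage(
        values=values,
        theta_p=theta_p,
        grid_spacing_mm=grid_spacing_mm,
        origin_mm=origin_mm,
        valid_mask=valid_mask,
    )


def nsdi_from_strain(strain: StrainTensorField) -> NSDIImage:
    """Convenience: principal angle + normalization in one call."""
    theta = principal_angle(strain)
    return nsdi(theta, strain.grid_spacing_mm, strain.origin_mm, strain.valid_mask.copy())


def make_outside_band(inside_mask: np.ndarray) -> np.ndarray:
    """Equal-area band of pixels surrounding ``inside_mask``.

    The band consists of the N outside pixels closest (Euclidean distance,
    ties broken by flat index) to the inside region, where N is the inside
    pixel count, so its area matches the inside area exactly.  Raises when
    the lesion touches the image border or the band would leave the image.
    """
    from scipy.ndimage import distance_transform_edt

    inside = np.asarray(inside_mask, dtype=bool)
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError("inside mask is empty")
    edge = np.zeros_like(inside)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if np.any(inside & edge):
        raise ValueError("lesion touches the image border; crop a larger margin")
    dist = distance_transform_edt(~inside)
    outside_idx = np.flatnonzero(~inside.ravel())
    order = np.lexsort((outside_idx, dist.ravel()[outside_idx]))
    chosen = outside_idx[order[:n_in]]
    if chosen.size < n_in:
        raise ValueError("not enough outside pixels for an equal-area band")
    band = np.zeros(inside.size, dtype=bool)
    band[chosen] = True
    band = band.reshape(inside.shape)
    if np.any(band & edge):
        raise ValueError("equal-area band reaches the image border; crop a larger margin")
    return band


def roi_stats(img: NSDIImage, roi: LesionROI) -> Tuple[float, float]:
    """Mean NSDI inside the lesion and in the equal-area outside band."""
    inside = roi.inside_mask(img.shape, img.grid_spacing_mm, img.origin_mm)
    band = make_outside_band(inside)
    inside &= img.valid_mask
    band &= img.valid_mask
    if not inside.any():
        raise ValueError("inside mask empty after intersection with valid pixels")
    if not band.any():
        raise ValueError("outside band mask empty after intersection with valid pixels")
    return float(img.values[inside].mean()), float(img.values[band].mean())


def size_ratio(
    strain_contour: np.ndarray, bmode_contour: np.ndarray, method: str = "area"
) -> float:
    """Lesion size on the strain elastogram over its size on B-mode.

    ``method='area'`` (default) uses polygon areas; ``method='length'``
    uses the maximum caliper length of each contour.
    """
    p_strain = _check_polygon(strain_contour, "strain_contour")
    p_bmode = _check_polygon(bmode_contour, "bmode_contour")
    if method == "area":
        if p_bmode.area == 0.0:
            raise ValueError("degenerate (zero-area) B-mode contour")
        return float(p_strain.area / p_bmode.area)
    if method == "length":

        def caliper(c):
            c = np.asarray(c, float)
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            return float(d.max())

        lb = caliper(bmode_contour)
        if lb == 0.0:
            raise ValueError("degenerate (zero-length) B-mode contour")
        return caliper(strain_contour) / lb
    raise ValueError("method must be 'area' or 'length'")
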