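"""Block-matching speckle tracking and multistep displacement accumulation.

Frame-to-frame motion is estimated by exhaustive normalized cross
correlation (NCC) of an RF kernel (default 1.5 mm lateral x 1.8 mm axial,
about one beam width by six wavelengths at 7.5 MHz) over a local search
region, with a three-point parabolic fit per axis refining the peak to
sub-sample precision.  Frame-to-frame fields are then accumulated into the
first frame's coordinate system: each material point starting on the
first-frame grid is advected through every intermediate field, which is
evaluated at the point's current position by cubic B-spline interpolation,
and the per-step motions are summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert
from skimage.feature import match_template

from .fields import DisplacementField
from .usim_rf import RFFrameSequence

__all__ = ["TrackingParams", "track_pair", "subsample_peak", "accumulate", "track_sequence"]

logger = logging.getLogger(__name__)


@dataclass
class TrackingParams:
    kernel_lateral_mm: float = 1.5
    kernel_axial_mm: float = 1.8
    search_axial_mm: float = 1.0
    search_lateral_mm: float = 0.6
    grid_step_axial_mm: float = 0.2
    grid_step_lateral_mm: Optional[float] = None  # None -> one beam pitch
    min_correlation: float = 0.5
    #: replace estimates deviating from the local 5x5 median by more than
    #: this many samples (RF correlation has carrier-cycle sidelobes that
    #: occasionally capture the peak); None disables the pass
    median_outlier_samples: Optional[float] = 1.0

    def __post_init__(self) -> None:
        if min(self.kernel_lateral_mm, self.kernel_axial_mm) <= 0:
            raise ValueError("kernel sizes must be positive")
        if min(self.search_axial_mm, self.search_lateral_mm) <= 0:
            raise ValueError("search sizes must be positive")
        if not (0.0 < self.min_correlation < 1.0):
            raise ValueError("min_correlation must lie in (0, 1)")


def subsample_peak(patch: np.ndarray) -> Tuple[float, float]:
    """Sub-sample peak offset from a 3x3 correlation patch.

    The center must be the integer maximum. Each axis is refined by the
    vertex of the parabola through the three collinear values; a flat
    (zero-denominator) axis yields 0 and offsets are clamped to [-0.5, 0.5].
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (3, 3):
        raise ValueError("subsample_peak expects a 3x3 patch")

    def vertex(cm, c0, cp):
        denom = 2.0 * (2.0 * c0 - cm - cp)
        if denom == 0.0:
            return 0.0
        return float(np.clip((cp - cm) / denom, -0.5, 0.5))

    d_ax = vertex(patch[0, 1], patch[1, 1], patch[2, 1])
    d_lat = vertex(patch[1, 0], patch[1, 1], patch[1, 2])
    return d_ax, d_lat


def track_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    params: TrackingParams,
    axial_spacing_mm: float,
    lateral_spacing_mm: float,
) -> DisplacementField:
    """NCC block matching from ``frame_a`` to ``frame_b``.

    Returns a *measured* displacement field on a regular grid of nodes.
    Pixels are masked invalid when the peak correlation falls below
    ``min_correlation``, the peak sits on the search border (no sub-sample
    refinement possible), or the kernel has zero variance.

    The RF correlation surface oscillates at the carrier and its sidelobes
    one cycle away can rival the true peak; the integer lag is therefore
    selected near the peak of the *envelope* correlation (which is unimodal)
    and only refined to sub-sample precision on the RF correlation.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    nz, nx = a.shape
    dz, dx = float(axial_spacing_mm), float(lateral_spacing_mm)

    ka = max(1, int(round(params.kernel_axial_mm / dz / 2.0)))
    kl = max(1, int(round(params.kernel_lateral_mm / dx / 2.0)))
    sa = max(1, int(round(params.search_axial_mm / dz)))
    sl = max(1, int(round(params.search_lateral_mm / dx)))
    if 2 * (ka + sa) + 1 > nz or 2 * (kl + sl) + 1 > nx:
        raise ValueError("kernel plus search region exceeds the frame")

    step_r = max(1, int(round(params.grid_step_axial_mm / dz)))
    step_c = max(
        1,
        int(round((params.grid_step_lateral_mm or lateral_spacing_mm) / dx)),
    )
    r0, r1 = ka + sa, nz - ka - sa - 1
    c0, c1 = kl + sl, nx - kl - sl - 1
    rows = np.arange(r0, r1 + 1, step_r)
    cols = np.arange(c0, c1 + 1, step_c)

    env_a = np.abs(hilbert(a, axis=0))
    env_b = np.abs(hilbert(b, axis=0))

    u = np.zeros((rows.size, cols.size))
    v = np.zeros((rows.size, cols.size))
    q = np.zeros((rows.size, cols.size))
    valid = np.ones((rows.size, cols.size), dtype=bool)

    for ri, r in enumerate(rows):
        for ci, c in enumerate(cols):
            tpl = a[r - ka : r + ka + 1, c - kl : c + kl + 1]
            if tpl.std() == 0.0:
                valid[ri, ci] = False
                continue
            win = b[r - ka - sa : r + ka + sa + 1, c - kl - sl : c + kl + sl + 1]
            ncc = match_template(win, tpl)  # (2 sa + 1, 2 sl + 1)
            ewin = env_b[r - ka - sa : r + ka + sa + 1, c - kl - sl : c + kl + sl + 1]
            etpl = env_a[r - ka : r + ka + 1, c - kl : c + kl + 1]
            if etpl.std() > 0.0:
                ncc_env = match_template(ewin, etpl)
                pe = np.unravel_index(np.argmax(ncc_env), ncc_env.shape)
                # keep the RF peak within half a carrier cycle of the
                # envelope peak: mask everything farther than 2 samples
                gate = np.full(ncc.shape, -np.inf)
                a0, a1 = max(pe[0] - 2, 0), min(pe[0] + 3, ncc.shape[0])
                gate[a0:a1, :] = 0.0
                ncc_gated = ncc + gate
            else:
                ncc_gated = ncc
            pk = np.unravel_index(np.argmax(ncc_gated), ncc.shape)
            peak = float(ncc[pk])
            q[ri, ci] = peak
            on_border = (
                pk[0] == 0 or pk[0] == ncc.shape[0] - 1 or pk[1] == 0 or pk[1] == ncc.shape[1] - 1
            )
            if peak < params.min_correlation or on_border:
                valid[ri, ci] = False
                u[ri, ci] = (pk[0] - sa) * dz
                v[ri, ci] = (pk[1] - sl) * dx
                continue
            d_ax, d_lat = subsample_peak(ncc[pk[0] - 1 : pk[0] + 2, pk[1] - 1 : pk[1] + 2])
            u[ri, ci] = (pk[0] - sa + d_ax) * dz
            v[ri, ci] = (pk[1] - sl + d_lat) * dx

    if params.median_outlier_samples is not None and min(u.shape) >= 5:
        thr = params.median_outlier_samples
        med_u = ndimage.median_filter(u, size=5)
        med_v = ndimage.median_filter(v, size=5)
        hop = (np.abs(u - med_u) > thr * dz) | (np.abs(v - med_v) > thr * dx)
        n_hop = int(np.count_nonzero(hop))
        if n_hop:
            logger.debug("track_pair: median pass replaced %d peak-hop estimates", n_hop)
            u[hop] = med_u[hop]
            v[hop] = med_v[hop]

    return DisplacementField(
        u_axial=u,
        v_lateral=v,
        grid_spacing_mm=(step_r * dz, step_c * dx),
        origin_mm=(rows[0] * dz, cols[0] * dx),
        valid_mask=valid,
        state="measured",
        quality=q,
    )


def _fill_invalid(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid value (for interpolation)."""
    if mask.all():
        return arr
    if not mask.any():
        return np.zeros_like(arr)
    idx = ndimage.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return arr[tuple(idx)]


def accumulate(fields: Sequence[DisplacementField]) -> DisplacementField:
    """Sum frame-to-frame fields along material trajectories.

    All fields must share the grid. Material points start at the
    first-frame grid nodes; each step's displacement is sampled at the
    point's current deformed position (cubic B-spline) and added.  A
    trajectory is invalid as soon as it leaves the grid or lands on an
    invalid pixel of any step.
    """
    if len(fields) == 0:
        raise ValueError("accumulate requires at least one field")
    f0 = fields[0]
    for f in fields[1:]:
        if f.shape != f0.shape or f.grid_spacing_mm != f0.grid_spacing_mm:
            raise ValueError("all fields must share grid shape and spacing")
    if len(fields) == 1:
        return f0

    ny, nx = f0.shape
    sy, sx = f0.grid_spacing_mm
    # positions in grid-index coordinates
    py, px = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij")
    total_u = np.zeros((ny, nx))
    total_v = np.zeros((ny, nx))
    valid = np.ones((ny, nx), dtype=bool)

    for f in fields:
        uu = _fill_invalid(f.u_axial, f.valid_mask)
        vv = _fill_invalid(f.v_lateral, f.valid_mask)
        in_grid = (py >= 0) & (py <= ny - 1) & (px >= 0) & (px <= nx - 1)
        iy = np.clip(np.round(py), 0, ny - 1).astype(int)
        ix = np.clip(np.round(px), 0, nx - 1).astype(int)
        valid &= in_grid & f.valid_mask[iy, ix]
        du = ndimage.map_coordinates(uu, [py, px], order=3, mode="nearest")
        dv = ndimage.map_coordinates(vv, [py, px], order=3, mode="nearest")
        total_u += du
        total_v += dv
        py = py + du / sy
        px = px + dv / sx

    return DisplacementField(
        u_axial=total_u,
        v_lateral=total_v,
        grid_spacing_mm=f0.grid_spacing_mm,
        origin_mm=f0.origin_mm,
        valid_mask=valid,
        state="measured",
    )


def track_sequence(seq: RFFrameSequence, params: TrackingParams) -> DisplacementField:
    """Track all adjacent frame pairs and accumulate to the first frame."""
    if seq.n_frames < 2:
        raise ValueError("tracking requires at least two frames")
    dz = seq.axial_sample_spacing_mm
    dx = seq.beam_pitch_mm
    fields: List[DisplacementField] = []
    for i in range(seq.n_frames - 1):
        f = track_pair(seq.frames[i], seq.frames[i + 1], params, dz, dx)
        frac_invalid = 1.0 - f.valid_mask.mean()
        logger.info(
            "pair %d->%d: median quality %.3f, %.1f%% invalid",
            i,
            i + 1,
            float(np.median(f.quality)),
            100 * frac_invalid,
        )
        if frac_invalid > 0.5:
            logger.warning("pair %d->%d has more than 50%% invalid pixels", i, i + 1)
        fields.append(f)
    return accumulate(fields)
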