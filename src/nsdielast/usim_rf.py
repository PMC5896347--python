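"""Convolution-model RF speckle simulator.

Renders beamformed radio-frequency (RF) frames from a random scatterer
field: each scatterer contributes its amplitude times a separable point
spread function (Gaussian-envelope cosine along the beam at the transducer
center frequency, Gaussian across beams). With >= 10 scatterers per
resolution cell the envelope statistics are Rayleigh (fully developed
speckle), which is what correlation-based speckle tracking operates on.

Pre/post-compression frame pairs are produced by moving every scatterer by
the ground-truth displacement interpolated at its position and re-rendering,
so the simulated motion is exact rather than image-resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .fields import DisplacementField

__all__ = [
    "ScattererField",
    "RFFrameSequence",
    "PSFParams",
    "AcquisitionParams",
    "make_scatterers",
    "render_frame",
    "deform_and_render",
    "render_sequence",
]

logger = logging.getLogger(__name__)


@dataclass
class ScattererField:
    """Point scatterers: (axial, lateral) positions in mm, normal amplitudes."""

    positions_mm: np.ndarray  # (n, 2) as (axial, lateral)
    amplitudes: np.ndarray  # (n,)
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        if self.positions_mm.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("positions and amplitudes must have equal length")

    @property
    def n(self) -> int:
        return self.amplitudes.shape[0]


@dataclass
class AcquisitionParams:
    """Linear-array acquisition metadata."""

    sampling_frequency_hz: float = 40.0e6
    center_frequency_hz: float = 7.5e6
    beam_pitch_mm: float = 0.2
    sound_speed_m_s: float = 1540.0
    depth_mm: float = 40.0
    width_mm: float = 40.0

    @property
    def axial_sample_spacing_mm(self) -> float:
        # pulse-echo: one RF sample spans c / (2 fs) of depth
        return self.sound_speed_m_s / (2.0 * self.sampling_frequency_hz) * 1e3

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / self.center_frequency_hz * 1e3

    @property
    def n_samples(self) -> int:
        return int(round(self.depth_mm / self.axial_sample_spacing_mm)) + 1

    @property
    def n_beams(self) -> int:
        return int(round(self.width_mm / self.beam_pitch_mm)) + 1


@dataclass
class PSFParams:
    """Separable point-spread function.

    ``axial_fwhm_mm`` is the full width at half maximum of the Gaussian
    envelope of the axial cosine burst.  The default 0.3 mm corresponds to
    roughly a 1.5-cycle pulse-echo burst at 7.5 MHz (about 50% fractional
    bandwidth, typical of imaging transducers); much longer, narrowband
    envelopes produce correlation sidelobes one carrier cycle away that are
    nearly as tall as the true peak and defeat correlation tracking.
    ``lateral_fwhm_mm`` approximates the -6 dB beam width.
    """

    axial_fwhm_mm: float = 0.3
    lateral_fwhm_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.axial_fwhm_mm <= 0 or self.lateral_fwhm_mm <= 0:
            raise ValueError("PSF widths must be positive")


@dataclass
class RFFrameSequence:
    """Stack of RF frames (axial sample x beam line) with shared metadata."""

    frames: np.ndarray  # (N, n_samples, n_beams)
    sampling_frequency_hz: float
    center_frequency_hz: float
    beam_pitch_mm: float
    sound_speed_m_s: float = 1540.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (N, samples, beams) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def axial_sample_spacing_mm(self) -> float:
        return self.sound_speed_m_s / (2.0 * self.sampling_frequency_hz) * 1e3


def make_scatterers(
    domain_height_mm: float,
    domain_width_mm: float,
    density_per_mm2: float = 40.0,
    seed: int = 0,
) -> ScattererField:
    """Draw a uniform random scatterer field, reproducible from ``seed``.

    The expected count is ``density x area``; the realized count is Poisson
    so that sub-regions are statistically independent. Amplitudes are
    standard normal. A zero-area domain yields an empty field.
    """
    if density_per_mm2 <= 0:
        raise ValueError("density_per_mm2 must be positive")
    if domain_height_mm < 0 or domain_width_mm < 0:
        raise ValueError("domain dimensions must be non-negative")
    rng = np.random.default_rng(seed)
    area = domain_height_mm * domain_width_mm
    n = int(rng.poisson(density_per_mm2 * area)) if area > 0 else 0
    ax = rng.uniform(0.0, domain_height_mm, n) if n else np.empty(0)
    lat = rng.uniform(0.0, domain_width_mm, n) if n else np.empty(0)
    amp = rng.standard_normal(n)
    return ScattererField(np.column_stack([ax, lat]) if n else np.empty((0, 2)), amp, seed=seed)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def render_frame(
    scatterers: ScattererField,
    acq: AcquisitionParams,
    psf: Optional[PSFParams] = None,
    chunk: int = 2048,
) -> np.ndarray:
    """Render one RF frame by exact per-scatterer PSF summation.

    Each scatterer adds amplitude x [Gaussian-envelope cos at the axial RF
    spatial frequency 2 fc / c] x [lateral Gaussian] evaluated analytically
    on the sample/beam grid; no gridding or resampling is involved, so
    sub-sample scatterer motion is rendered exactly.
    """
    psf = psf or PSFParams()
    dz = acq.axial_sample_spacing_mm
    dx = acq.beam_pitch_mm
    nz, nx_ = acq.n_samples, acq.n_beams
    sig_ax = _fwhm_to_sigma(psf.axial_fwhm_mm)
    sig_lat = _fwhm_to_sigma(psf.lateral_fwhm_mm)
    half_ax = int(np.ceil(4.0 * sig_ax / dz))
    half_lat = int(np.ceil(4.0 * sig_lat / dx))
    if 2 * half_ax + 1 > nz or 2 * half_lat + 1 > nx_:
        raise ValueError("PSF support exceeds the frame; enlarge the frame or shrink the PSF")
    # axial RF oscillation: spatial frequency 2 fc / c (pulse-echo)
    k_ax = 2.0 * np.pi * (2.0 * acq.center_frequency_hz / acq.sound_speed_m_s) * 1e-3  # rad/mm

    frame = np.zeros((nz, nx_))
    pos = scatterers.positions_mm
    amp = scatterers.amplitudes
    off_ax = np.arange(-half_ax, half_ax + 1)
    off_lat = np.arange(-half_lat, half_lat + 1)
    for s in range(0, scatterers.n, chunk):
        p = pos[s : s + chunk]
        a = amp[s : s + chunk]
        iz = np.round(p[:, 0] / dz).astype(np.int64)
        ix = np.round(p[:, 1] / dx).astype(np.int64)
        zi = iz[:, None] + off_ax[None, :]  # (m, wz)
        xi = ix[:, None] + off_lat[None, :]  # (m, wx)
        r_ax = zi * dz - p[:, 0:1]
        r_lat = xi * dx - p[:, 1:2]
        prof_ax = np.exp(-0.5 * (r_ax / sig_ax) ** 2) * np.cos(k_ax * r_ax)
        prof_lat = np.exp(-0.5 * (r_lat / sig_lat) ** 2)
        contrib = a[:, None, None] * prof_ax[:, :, None] * prof_lat[:, None, :]
        ok_z = (zi >= 0) & (zi < nz)
        ok_x = (xi >= 0) & (xi < nx_)
        zi_c = np.clip(zi, 0, nz - 1)
        xi_c = np.clip(xi, 0, nx_ - 1)
        contrib *= ok_z[:, :, None] & ok_x[:, None, :]
        np.add.at(
            frame,
            (np.broadcast_to(zi_c[:, :, None], contrib.shape),
             np.broadcast_to(xi_c[:, None, :], contrib.shape)),
            contrib,
        )
    return frame


def _displace_scatterers(
    scatterers: ScattererField, displacement: DisplacementField
) -> Tuple[ScattererField, int]:
    """Move scatterers by the bicubically interpolated displacement.

    Scatterers falling on invalid-masked regions of the displacement grid
    are dropped (count returned).
    """
    ys = displacement.axial_coords_mm()
    xs = displacement.lateral_coords_mm()
    p = scatterers.positions_mm
    in_grid = (
        (p[:, 0] >= ys[0]) & (p[:, 0] <= ys[-1]) & (p[:, 1] >= xs[0]) & (p[:, 1] <= xs[-1])
    )
    # invalid where the nearest grid pixel is masked out
    iy = np.clip(np.round((p[:, 0] - ys[0]) / displacement.grid_spacing_mm[0]), 0, len(ys) - 1).astype(int)
    ix = np.clip(np.round((p[:, 1] - xs[0]) / displacement.grid_spacing_mm[1]), 0, len(xs) - 1).astype(int)
    keep = in_grid & displacement.valid_mask[iy, ix]
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        logger.info("deform_and_render: dropped %d scatterers outside the valid grid", dropped)
    p = p[keep]
    su = RectBivariateSpline(ys, xs, displacement.u_axial, kx=3, ky=3)
    sv = RectBivariateSpline(ys, xs, displacement.v_lateral, kx=3, ky=3)
    du = su.ev(p[:, 0], p[:, 1])
    dv = sv.ev(p[:, 0], p[:, 1])
    moved = np.column_stack([p[:, 0] + du, p[:, 1] + dv])
    return ScattererField(moved, scatterers.amplitudes[keep], seed=scatterers.seed), dropped


def deform_and_render(
    scatterers: ScattererField,
    displacement: DisplacementField,
    acq: AcquisitionParams,
    psf: Optional[PSFParams] = None,
) -> np.ndarray:
    """Render the post-deformation frame for a given displacement field."""
    moved, _ = _displace_scatterers(scatterers, displacement)
    return render_frame(moved, acq, psf)


def render_sequence(
    scatterers: ScattererField,
    displacements: Sequence[DisplacementField],
    acq: AcquisitionParams,
    psf: Optional[PSFParams] = None,
) -> RFFrameSequence:
    """Render frame 0 (undeformed) plus one frame per cumulative field.

    ``displacements[i]`` is the *total* displacement from the undeformed
    state to load step i+1; fields are expected in monotonically increasing
    load order (checked by mean |axial| magnitude; violations warn only,
    since freehand loading in practice is not perfectly monotonic).
    """
    mags = [float(np.mean(np.abs(d.u_axial[d.valid_mask]))) for d in displacements]
    if any(b < a for a, b in zip(mags, mags[1:])):
        logger.warning("render_sequence: displacement magnitudes are not monotonic")
    frames = [render_frame(scatterers, acq, psf)]
    for d in displacements:
        frames.append(deform_and_render(scatterers, d, acq, psf))
    return RFFrameSequence(
        frames=np.stack(frames),
        sampling_frequency_hz=acq.sampling_frequency_hz,
        center_frequency_hz=acq.center_frequency_hz,
        beam_pitch_mm=acq.beam_pitch_mm,
        sound_speed_m_s=acq.sound_speed_m_s,
    )
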