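"""HDF5 container layout (with an NPZ fallback) for pipeline artifacts.

Layout:

* ``/rf/frames`` (N, samples, beams) with attrs ``fs_hz``, ``fc_hz``,
  ``pitch_mm``, ``c_m_s``;
* ``/truth/u_axial``, ``/truth/v_lateral``, ``/truth/strain/{exx,eyy,exy}``
  with grid spacing / origin attrs;
* ``/disp/{u,v,quality,mask}`` with a ``state`` attr;
* ``/strain/{exx,eyy,exy}`` and ``/nsdi/{values,theta_p}``.

Contours are read/written as two-column CSV vertex lists with an
``x_mm,y_mm`` header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple, Union

import h5py
import numpy as np

from .fields import DisplacementField, NSDIImage, StrainTensorField
from .usim_rf import RFFrameSequence

__all__ = [
    "save_rf",
    "load_rf",
    "save_displacement",
    "load_displacement",
    "save_strain",
    "save_nsdi",
    "save_truth",
    "write_contour_csv",
    "read_contour_csv",
]

PathLike = Union[str, Path]


def _grid_attrs(g, spacing, origin) -> None:
    g.attrs["grid_spacing_mm"] = np.asarray(spacing, dtype=float)
    g.attrs["origin_mm"] = np.asarray(origin, dtype=float)


def save_rf(path: PathLike, seq: RFFrameSequence) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            frames=seq.frames,
            fs_hz=seq.sampling_frequency_hz,
            fc_hz=seq.center_frequency_hz,
            pitch_mm=seq.beam_pitch_mm,
            c_m_s=seq.sound_speed_m_s,
        )
        return
    with h5py.File(path, "a") as f:
        g = f.require_group("rf")
        if "frames" in g:
            del g["frames"]
        d = g.create_dataset("frames", data=seq.frames)
        d.attrs["fs_hz"] = seq.sampling_frequency_hz
        d.attrs["fc_hz"] = seq.center_frequency_hz
        d.attrs["pitch_mm"] = seq.beam_pitch_mm
        d.attrs["c_m_s"] = seq.sound_speed_m_s


def load_rf(path: PathLike) -> RFFrameSequence:
    path = Path(path)
    if path.suffix == ".npz":
        z = np.load(path)
        return RFFrameSequence(
            frames=z["frames"],
            sampling_frequency_hz=float(z["fs_hz"]),
            center_frequency_hz=float(z["fc_hz"]),
            beam_pitch_mm=float(z["pitch_mm"]),
            sound_speed_m_s=float(z["c_m_s"]),
        )
    with h5py.File(path, "r") as f:
        d = f["rf/frames"]
        return RFFrameSequence(
            frames=d[...],
            sampling_frequency_hz=float(d.attrs["fs_hz"]),
            center_frequency_hz=float(d.attrs["fc_hz"]),
            beam_pitch_mm=float(d.attrs["pitch_mm"]),
            sound_speed_m_s=float(d.attrs["c_m_s"]),
        )


def save_displacement(path: PathLike, field: DisplacementField, group: str = "disp") -> None:
    with h5py.File(Path(path), "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("u", data=field.u_axial)
        g.create_dataset("v", data=field.v_lateral)
        g.create_dataset("mask", data=field.valid_mask)
        if field.quality is not None:
            g.create_dataset("quality", data=field.quality)
        g.attrs["state"] = field.state
        _grid_attrs(g, field.grid_spacing_mm, field.origin_mm)


def load_displacement(path: PathLike, group: str = "disp") -> DisplacementField:
    with h5py.File(Path(path), "r") as f:
        g = f[group]
        return DisplacementField(
            u_axial=g["u"][...],
            v_lateral=g["v"][...],
            grid_spacing_mm=tuple(g.attrs["grid_spacing_mm"]),
            origin_mm=tuple(g.attrs["origin_mm"]),
            valid_mask=g["mask"][...],
            state=str(g.attrs["state"]),
            quality=g["quality"][...] if "quality" in g else None,
        )


def save_strain(path: PathLike, strain: StrainTensorField, group: str = "strain") -> None:
    with h5py.File(Path(path), "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("exx", data=strain.exx)
        g.create_dataset("eyy", data=strain.eyy)
        g.create_dataset("exy", data=strain.exy)
        g.create_dataset("mask", data=strain.valid_mask)
        _grid_attrs(g, strain.grid_spacing_mm, strain.origin_mm)


def save_nsdi(path: PathLike, img: NSDIImage, group: str = "nsdi") -> None:
    with h5py.File(Path(path), "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("values", data=img.values)
        g.create_dataset("theta_p", data=img.theta_p)
        g.create_dataset("mask", data=img.valid_mask)
        _grid_attrs(g, img.grid_spacing_mm, img.origin_mm)


def save_truth(
    path: PathLike,
    field: DisplacementField,
    strain: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> None:
    """Write ground-truth displacement (and optional strain) datasets."""
    with h5py.File(Path(path), "a") as f:
        if "truth" in f:
            del f["truth"]
        g = f.create_group("truth")
        g.create_dataset("u_axial", data=field.u_axial)
        g.create_dataset("v_lateral", data=field.v_lateral)
        g.create_dataset("mask", data=field.valid_mask)
        _grid_attrs(g, field.grid_spacing_mm, field.origin_mm)
        if strain is not None:
            gs = g.create_group("strain")
            for name, arr in zip(("exx", "eyy", "exy"), strain):
                gs.create_dataset(name, data=arr)


def write_contour_csv(path: PathLike, contour: np.ndarray) -> None:
    contour = np.asarray(contour, dtype=float)
    header = "x_mm,y_mm"
    np.savetxt(Path(path), contour, delimiter=",", header=header, comments="")


def read_contour_csv(path: PathLike) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", skiprows=1).reshape(-1, 2)
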