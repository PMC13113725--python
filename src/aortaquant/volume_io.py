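"""Volumetric image container and NIfTI/NRRD I/O with physical-space metadata.

All world coordinates inside the package are LPS millimetres; voxel
indices are 0-based and a voxel's world position is its center.  Any
format-native convention (e.g. nibabel's RAS affines) is converted at
the reader/writer boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from . import _nrrd

__all__ = ["ImageVolume", "read_volume", "write_volume", "resample_isotropic"]

# RAS <-> LPS axis flips
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ImageVolume:
    """A 3D scalar or label image with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Voxel values indexed ``data[i, j, k]``.
    spacing : (3,) float
        Millimetres per voxel along each index axis; all positive.
    origin : (3,) float
        World (LPS, mm) position of the center of voxel (0, 0, 0).
    direction : (3, 3) float
        Orthonormal matrix whose *columns* give the world direction of
        each index axis; ``world = origin + direction @ (spacing * idx)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None
    direction: np.ndarray = None
    _: dataclass = field(init=False, default=None, repr=False)

    def __init__(self, data, spacing, origin=(0.0, 0.0, 0.0), direction=None):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"ImageVolume requires 3D data, got {data.ndim}D")
        spacing = np.asarray(spacing, dtype=float).reshape(3)
        if np.any(spacing <= 0):
            raise ValueError(f"spacing must be positive, got {tuple(spacing)}")
        origin = np.asarray(origin, dtype=float).reshape(3)
        if direction is None:
            direction = np.eye(3)
        direction = np.asarray(direction, dtype=float).reshape(3, 3)
        if abs(abs(np.linalg.det(direction)) - 1.0) > 1e-6 or \
                not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal (|det| = 1)")
        self.data = data
        self.spacing = spacing
        self.origin = origin
        self.direction = direction

    @property
    def shape(self):
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 LPS index-to-world affine (voxel centers)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        pts = (self.direction @ (idx * self.spacing).T).T + self.origin
        return pts if pts.shape[0] > 1 else pts[0]

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx = (self.direction.T @ (pts - self.origin).T).T / self.spacing
        return idx if idx.shape[0] > 1 else idx[0]

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.direction, other.direction, atol=atol))


def _split_affine(aff_lps: np.ndarray):
    m = aff_lps[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing[np.newaxis, :]
    return spacing, aff_lps[:3, 3].copy(), direction


def read_volume(path) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd/.nhdr) volume.

    Metadata is converted to the package's LPS millimetre convention;
    voxel values are returned unaltered.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        try:
            img = nib.load(path)
            data = np.asanyarray(img.dataobj)
            aff = img.affine
        except Exception as exc:  # nibabel raises a zoo of types
            raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
        spacing, origin, direction = _split_affine(_RAS2LPS @ aff)
        return ImageVolume(data, spacing, origin, direction)
    if lower.endswith((".nrrd", ".nhdr")):
        try:
            data, hdr = _nrrd.read(path)
        except IOError:
            raise
        except Exception as exc:
            raise IOError(f"could not read NRRD file {path}: {exc}") from exc
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
        flips = _nrrd.space_sign_flips(hdr.get("space", ""))
        if "space directions" in hdr:
            # rows of the header field are per-axis world vectors -> columns here
            m = hdr["space directions"].T * flips[:, np.newaxis]
        else:
            m = np.eye(3)
        origin = hdr.get("space origin", np.zeros(3)) * flips
        aff = np.eye(4)
        aff[:3, :3] = m
        aff[:3, 3] = origin
        spacing, origin, direction = _split_affine(aff)
        return ImageVolume(data, spacing, origin, direction)
    raise IOError(f"unsupported volume format: {path} "
                  "(expected .nii, .nii.gz, .nrrd or .nhdr)")


def write_volume(vol: ImageVolume, path) -> str:
    """Write *vol* to NIfTI or NRRD (chosen by extension); returns the path."""
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    if not os.access(parent, os.W_OK):
        raise IOError(f"destination not writable: {parent}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        aff_ras = _RAS2LPS @ vol.affine  # involution: same flip both ways
        img = nib.Nifti1Image(data, aff_ras)
        img.header.set_zooms(tuple(vol.spacing))
        nib.save(img, path)
        return path
    if lower.endswith(".nrrd"):
        sd = vol.direction * vol.spacing[np.newaxis, :]
        _nrrd.write(path, data, space_directions=sd, space_origin=vol.origin)
        return path
    raise IOError(f"unsupported volume format for writing: {path}")


def resample_isotropic(vol: ImageVolume, voxel_mm: float,
                       interp: str = "linear") -> ImageVolume:
    """Resample onto an isotropic grid of pitch *voxel_mm*.

    The output grid is anchored at the input origin (same direction
    matrix) and sized ``ceil(extent / voxel_mm)`` per axis, so the
    physical extent is preserved to within one voxel per axis.  Nearest
    interpolation never introduces label values absent from the input.
    """
    from scipy.ndimage import map_coordinates

    if voxel_mm <= 0:
        raise ValueError(f"voxel_mm must be positive, got {voxel_mm}")
    if interp not in ("nearest", "linear"):
        raise ValueError(f"interp must be 'nearest' or 'linear', got {interp!r}")
    order = 0 if interp == "nearest" else 1

    extent = np.asarray(vol.shape) * vol.spacing
    out_shape = np.maximum(np.ceil(extent / voxel_mm - 1e-9).astype(int), 1)
    # identical direction/origin -> index mapping is separable per axis
    scale = voxel_mm / vol.spacing
    coords = np.meshgrid(*(np.arange(n) * s for n, s in zip(out_shape, scale)),
                         indexing="ij")
    data = vol.data
    was_bool = data.dtype == bool
    if was_bool:
        data = data.astype(np.uint8)
    # edge clamp: the output grid may reach half a voxel past the last
    # source center while still inside the source's physical extent
    out = map_coordinates(data, coords, order=order, mode="nearest",
                          prefilter=False)
    if was_bool:
        out = out.astype(bool)
    return ImageVolume(out, np.full(3, float(voxel_mm)), vol.origin.copy(),
                       vol.direction.copy())
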