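"""Tissue-surface detection and surface-flattened en face plane extraction.

All co-registration in this toolkit happens on en face planes sampled at a
fixed depth *below the tissue surface* (100 um by convention), so the surface
must first be found per A-scan.  The detector is a per-column adaptive
first-crossing: the first depth at which the (axially median-filtered)
intensity exceeds a fraction of the column maximum, followed by lateral median
smoothing.  Columns whose maximum never rises above a global noise floor are
marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import NoSurfaceError, ValidationError
from .volume_io import OCTVolume

__all__ = ["SurfaceMap", "EnFacePlane", "detect_surface", "extract_enface"]


@dataclass
class SurfaceMap:
    """Per-lateral-position depth index of the first tissue voxel."""

    depth_index: np.ndarray  # (ny, nx) int
    valid: np.ndarray  # (ny, nx) bool

    def __post_init__(self):
        if self.depth_index.shape != self.valid.shape:
            raise ValidationError("depth_index and valid mask shapes differ")


@dataclass
class EnFacePlane:
    """A lateral (y, x) plane sampled at a fixed depth below the detected surface."""

    image: np.ndarray  # (ny, nx), NaN where no data
    valid: np.ndarray  # (ny, nx) bool
    depth_offset_um: float
    spacing_y_um: float
    spacing_x_um: float
    source_id: str | None = None

    def __post_init__(self):
        if self.image.shape != self.valid.shape:
            raise ValidationError("image and valid mask shapes differ")
        if self.depth_offset_um < 0:
            raise ValidationError("depth_offset_um must be >= 0")

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())


def detect_surface(
    vol: OCTVolume,
    smooth_um: float = 50.0,
    intensity_floor_fraction: float = 0.3,
    noise_floor_fraction: float = 0.05,
    axial_median: int = 3,
) -> SurfaceMap:
    """Find the first tissue voxel per A-scan.

    Parameters
    ----------
    smooth_um
        Lateral median-smoothing window applied to the detected depth map.
    intensity_floor_fraction
        Per-column threshold as a fraction of the column maximum (default 0.3).
    noise_floor_fraction
        Columns whose maximum is below this fraction of the volume maximum
        carry no surface and are marked invalid.

    Raises
    ------
    NoSurfaceError
        If no column anywhere in the volume rises above the noise floor.
    """
    inten = np.asarray(vol.intensity, dtype=float)
    inten = np.where(np.isfinite(inten), inten, 0.0)
    if axial_median > 1:
        inten = ndimage.median_filter(inten, size=(axial_median, 1, 1))
    col_max = inten.max(axis=0)
    global_max = col_max.max()
    if global_max <= 0:
        raise NoSurfaceError("volume contains no signal above zero")
    valid = col_max > noise_floor_fraction * global_max
    if not valid.any():
        raise NoSurfaceError("entire volume below the noise floor")
    thresh = intensity_floor_fraction * col_max
    above = inten >= thresh[None, :, :]
    # argmax gives the first True along z; columns with no crossing are invalid anyway
    depth = above.argmax(axis=0).astype(np.int64)
    valid &= above.any(axis=0)

    # lateral median smoothing of the depth map (fill invalid with the median first
    # so holes do not drag the filter)
    if valid.any():
        fill = int(np.median(depth[valid]))
    else:  # pragma: no cover - excluded by the noise-floor check above
        fill = 0
    depth_f = np.where(valid, depth, fill)
    ky = max(1, int(round(smooth_um / vol.spacing_y_um)))
    kx = max(1, int(round(smooth_um / vol.spacing_x_um)))
    ky += 1 - ky % 2  # odd sizes keep the filter centred
    kx += 1 - kx % 2
    if ky > 1 or kx > 1:
        depth_f = ndimage.median_filter(depth_f, size=(ky, kx))
    return SurfaceMap(depth_index=depth_f.astype(np.int64), valid=valid)


def extract_enface(
    vol: OCTVolume,
    surface: SurfaceMap,
    depth_offset_um: float = 100.0,
) -> EnFacePlane:
    """Sample the volume at a fixed offset below the detected surface.

    The offset is converted to whole voxels by nearest rounding (the 100 um
    convention is large against the few-um axial spacing, so axial
    interpolation is immaterial).  Positions where the offset runs past the
    bottom of the volume, or where no surface was found, are marked no-data.
    """
    if depth_offset_um < 0:
        raise ValidationError("depth_offset_um must be >= 0")
    nz, ny, nx = vol.shape
    if surface.depth_index.shape != (ny, nx):
        raise ValidationError("surface map lateral shape does not match the volume")
    off_vox = int(round(depth_offset_um / vol.spacing_z_um))
    z = surface.depth_index + off_vox
    valid = surface.valid & (z >= 0) & (z < nz)
    zc = np.clip(z, 0, nz - 1)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    img = np.asarray(vol.intensity, dtype=float)[zc, yy, xx]
    img = np.where(valid & np.isfinite(img), img, np.nan)
    valid = valid & np.isfinite(img)
    return EnFacePlane(
        image=img,
        valid=valid,
        depth_offset_um=float(depth_offset_um),
        spacing_y_um=vol.spacing_y_um,
        spacing_x_um=vol.spacing_x_um,
        source_id=vol.tile_id,
    )
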