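"""Tile planning and feather-blend stitching of benchtop (ex vivo) OCT tiles.

The benchtop scanner's lateral field of view (16 x 16 mm^2) is smaller than
many cavity shavings, so the specimen is translated on mechanical stages and
scanned at multiple positions; the tiles are then blended into one wide-field
volume.  Stage positions are trusted as hardware-accurate, so no cross-tile
registration is performed — blending is a weight-normalized linear feather
from each tile edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import PlanningError, ValidationError
from .volume_io import OCTVolume

__all__ = ["TilePlan", "plan_tiles", "stitch"]


@dataclass
class TilePlan:
    """Lateral stage positions (tile origins, um) covering a requested extent."""

    positions_um: list  # [(x, y), ...]
    tile_fov_um: tuple[float, float]
    min_overlap_um: float
    n_tiles: tuple[int, int]  # (nx, ny)


def _axis_count(extent: float, fov: float, step: float) -> int:
    """Smallest n with fov + (n-1) * step >= extent."""
    if fov >= extent:
        return 1
    return int(math.ceil((extent - fov) / step)) + 1


def plan_tiles(extent_um, tile_fov_um, step_um) -> TilePlan:
    """Plan evenly spaced, overlapping tile positions per axis.

    Scalars apply to both lateral axes.  ``step_um`` must be smaller than the
    field of view so adjacent tiles overlap.
    """
    ex, ey = (extent_um, extent_um) if np.isscalar(extent_um) else tuple(extent_um)
    fx, fy = (tile_fov_um, tile_fov_um) if np.isscalar(tile_fov_um) else tuple(tile_fov_um)
    sx, sy = (step_um, step_um) if np.isscalar(step_um) else tuple(step_um)
    for f, s in ((fx, sx), (fy, sy)):
        if s >= f:
            raise PlanningError(f"step {s} um >= tile field of view {f} um: tiles would not overlap")
        if f <= 0 or s <= 0:
            raise PlanningError("field of view and step must be positive")
    nx = _axis_count(ex, fx, sx)
    ny = _axis_count(ey, fy, sy)
    positions = [(i * sx, j * sy) for j in range(ny) for i in range(nx)]
    min_overlap = min(fx - sx, fy - sy) if (nx > 1 or ny > 1) else min(fx, fy)
    return TilePlan(positions_um=positions, tile_fov_um=(fx, fy), min_overlap_um=min_overlap, n_tiles=(nx, ny))


def stitch(tiles: list[OCTVolume], blend: str = "feather", feather_um: float | None = None) -> OCTVolume:
    """Blend tiles (with known origins) into a wide-field volume.

    Each contributing voxel is a weight-normalized average; weights rise
    linearly from each tile's lateral edge (feathering) so seams are smooth,
    and sum to one wherever at least one tile contributes.  Voxels covered by
    no tile are NaN (no-data).

    Raises
    ------
    ValidationError
        If tiles disagree in voxel spacing or depth extent.
    """
    if not tiles:
        raise ValidationError("no tiles to stitch")
    ref = tiles[0]
    for t in tiles[1:]:
        if (t.spacing_z_um, t.spacing_y_um, t.spacing_x_um) != (
            ref.spacing_z_um,
            ref.spacing_y_um,
            ref.spacing_x_um,
        ):
            raise ValidationError("all tiles must share voxel spacings")
        if t.nz != ref.nz:
            raise ValidationError("all tiles must share depth extent")
    if blend not in ("feather", "uniform"):
        raise ValidationError(f"unknown blend mode {blend!r}")

    sx, sy = ref.spacing_x_um, ref.spacing_y_um
    ox = [int(round(t.origin_um[0] / sx)) for t in tiles]
    oy = [int(round(t.origin_um[1] / sy)) for t in tiles]
    x0, y0 = min(ox), min(oy)
    x1 = max(o + t.shape[2] for o, t in zip(ox, tiles))
    y1 = max(o + t.shape[1] for o, t in zip(oy, tiles))
    nz = ref.nz
    num = np.zeros((nz, y1 - y0, x1 - x0), dtype=np.float64)
    den = np.zeros((y1 - y0, x1 - x0), dtype=np.float64)

    for t, oxi, oyi in zip(tiles, ox, oy):
        _, ny_t, nx_t = t.shape
        if blend == "uniform":
            w = np.ones((ny_t, nx_t))
        else:
            # linear ramp from each lateral edge; default feather width = half the
            # smallest overlap implied by tile placement, bounded by half the tile
            iy = np.minimum(np.arange(ny_t), np.arange(ny_t)[::-1]) + 1.0
            ix = np.minimum(np.arange(nx_t), np.arange(nx_t)[::-1]) + 1.0
            if feather_um is not None:
                fy = max(1.0, feather_um / sy)
                fx = max(1.0, feather_um / sx)
            else:
                fy = max(1.0, ny_t / 4)
                fx = max(1.0, nx_t / 4)
            w = np.minimum(iy / fy, 1.0)[:, None] * np.minimum(ix / fx, 1.0)[None, :]
        data = np.asarray(t.intensity, dtype=np.float64)
        wv = np.where(np.isfinite(data).all(axis=0), w, 0.0)
        ys = slice(oyi - y0, oyi - y0 + ny_t)
        xs = slice(oxi - x0, oxi - x0 + nx_t)
        num[:, ys, xs] += np.where(np.isfinite(data), data, 0.0) * wv[None]
        den[ys, xs] += wv

    covered = den > 0
    out = np.full_like(num, np.nan, dtype=np.float32)
    out[:, covered] = (num[:, covered] / den[covered]).astype(np.float32)
    return OCTVolume(
        intensity=out,
        spacing_z_um=ref.spacing_z_um,
        spacing_y_um=ref.spacing_y_um,
        spacing_x_um=ref.spacing_x_um,
        role="wide_field",
        origin_um=(x0 * sx, y0 * sy),
    )
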