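"""Mapping the wide-field OCT frame to bread-loaf histology sections.

Shavings are serially sectioned into ~4-5 mm slabs in the plane orthogonal to
the en face view, so each histology slide corresponds to a cross-sectional
B-scan.  Three steps connect the frames:

1. overlay the section grid (the cut lines) on the wide-field en face image,
   oriented by the inking code;
2. rescale each slide by its shrinkage correction factor
   ``c = fresh width / section width`` (one factor per slide — shrinkage
   varies across a shaving);
3. select the best-matching B-scan near each grid line by structural
   similarity, since warping means the cut lines are only approximate.

Similarity is the Dice overlap of binary solid-tissue maps rather than raw
intensity correlation: histology and OCT have unrelated intensity semantics,
but adipose/void versus solid structure is shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import ValidationError
from .surface_enface import EnFacePlane
from .volume_io import OCTVolume

__all__ = [
    "HistologySection",
    "SectionGrid",
    "overlay_grid",
    "shrinkage_factor",
    "match_bscan",
]


@dataclass
class HistologySection:
    """A 2-D (depth x width) histology structure image with its measured widths."""

    image: np.ndarray
    section_index: int
    fresh_width_um: float
    section_width_um: float
    spacing_z_um: float = 1.0
    spacing_x_um: float = 1.0
    line_y_um: float | None = None

    def __post_init__(self):
        if self.fresh_width_um <= 0 or self.section_width_um <= 0:
            raise ValidationError("section widths must be positive")

    @property
    def correction_factor(self) -> float:
        """Shrinkage correction c = fresh width / section width (>= 1 for shrinkage)."""
        return self.fresh_width_um / self.section_width_um


@dataclass
class SectionGrid:
    """Cut-line positions (um along y) on the wide-field en face image."""

    line_positions_um: np.ndarray
    spacing_um: float
    orientation_code: str


def specimen_mask_from_plane(plane: EnFacePlane, threshold_fraction: float = 0.1) -> np.ndarray:
    """Tissue-vs-background mask: valid pixels above a fraction of the bright level."""
    img = np.where(plane.valid, plane.image, np.nan)
    bright = np.nanpercentile(img, 99.0)
    mask = plane.valid & (plane.image > threshold_fraction * bright)
    # closing fills small holes; the union keeps border pixels the closing's
    # zero-padded erosion would otherwise shave off
    mask = mask | ndimage.binary_closing(mask, iterations=2)
    return mask


def overlay_grid(
    wide_field_enface: EnFacePlane,
    spacing_um: float,
    orientation_code: str = "standard",
) -> SectionGrid:
    """Place equally spaced section lines across the specimen along y.

    The first line sits at half-spacing from the specimen edge; a flipped
    orientation code mirrors the line order about the specimen midline
    (the inked margins fix which end was cut first).

    Raises
    ------
    ValidationError
        If the spacing exceeds the specimen extent.
    """
    if orientation_code not in ("standard", "flipped"):
        raise ValidationError(f"unknown orientation code {orientation_code!r}")
    mask = specimen_mask_from_plane(wide_field_enface)
    rows = np.where(mask.any(axis=1))[0]
    if rows.size == 0:
        raise ValidationError("no specimen found in the en face plane")
    y0 = rows[0] * wide_field_enface.spacing_y_um
    y1 = (rows[-1] + 1) * wide_field_enface.spacing_y_um
    extent = y1 - y0
    if spacing_um > extent:
        raise ValidationError(
            f"section spacing {spacing_um} um exceeds specimen extent {extent:.0f} um"
        )
    lines = np.arange(y0 + spacing_um / 2, y1, spacing_um)
    if orientation_code == "flipped":
        lines = (y0 + y1) - lines[::-1]
    return SectionGrid(line_positions_um=lines, spacing_um=spacing_um, orientation_code=orientation_code)


def shrinkage_factor(fresh_width_um: float, section_width_um: float) -> float:
    """Correction factor c = fresh width / section width.

    Histology processing shrinks tissue; scaling a slide's lateral dimensions
    by ``c`` restores fresh-tissue scale before matching against OCT.
    """
    if fresh_width_um <= 0 or section_width_um <= 0:
        raise ValidationError("widths must be positive")
    return fresh_width_um / section_width_um


def _structure_map(img: np.ndarray, threshold_fraction: float = 0.3) -> np.ndarray:
    """Binary solid-tissue map: bright structure vs adipose interiors / voids."""
    finite = img[np.isfinite(img)]
    if finite.size == 0 or finite.max() <= 0:
        return np.zeros(img.shape, dtype=bool)
    ref = np.percentile(finite, 99.0)
    return np.where(np.isfinite(img), img, 0.0) > threshold_fraction * ref


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    total = a.sum() + b.sum()
    if total == 0:
        return 0.0
    return 2.0 * inter / total


def match_bscan(
    section: HistologySection,
    wide_field: OCTVolume,
    grid_line_um: float,
    search_halfwidth_um: float = 1000.0,
    correction_factor: float | None = None,
) -> tuple[int, float]:
    """Find the B-scan best matching a histology section near its grid line.

    The section is first rescaled to fresh-tissue dimensions by its shrinkage
    correction factor, then compared with every (z, x) B-scan within
    ``search_halfwidth_um`` of the grid line by Dice overlap of binary
    solid-structure maps.  Ties break toward the grid line.  With a half-width
    of 0 the grid-line B-scan itself is returned.

    Returns
    -------
    (best_index, score)
    """
    nz, ny, nx = wide_field.shape
    sp_y = wide_field.spacing_y_um
    line_idx = int(round(grid_line_um / sp_y - 0.5))
    if not (0 <= line_idx < ny):
        raise ValidationError(f"grid line at {grid_line_um} um outside the volume")
    half = int(round(search_halfwidth_um / sp_y))
    lo, hi = line_idx - half, line_idx + half
    if lo < 0 or hi >= ny:
        raise ValidationError("search window extends outside the volume")

    c = correction_factor if correction_factor is not None else section.correction_factor
    img = section.image.astype(np.float64)
    if c != 1.0:
        img = ndimage.zoom(img, (1.0, c), order=1)
    # resample to the wide-field grid if pixel sizes differ
    fz = section.spacing_z_um / wide_field.spacing_z_um
    fx = section.spacing_x_um / wide_field.spacing_x_um
    if abs(fz - 1) > 1e-9 or abs(fx - 1) > 1e-9:
        img = ndimage.zoom(img, (fz, fx), order=1)
    sec_bin = _structure_map(img)

    data = np.where(np.isfinite(wide_field.intensity), wide_field.intensity, 0.0)

    def _common(a: np.ndarray, b: np.ndarray):
        h = min(a.shape[0], b.shape[0])
        w = min(a.shape[1], b.shape[1])
        return a[:h, :w], b[:h, :w]

    best_idx, best_score = line_idx, -1.0
    order = sorted(range(lo, hi + 1), key=lambda i: (abs(i - line_idx), i))
    for i in order:
        bs_bin = _structure_map(data[:, i, :])
        a, b = _common(sec_bin, bs_bin)
        score = _dice(a, b)
        if score > best_score + 1e-12:
            best_idx, best_score = i, score
    return best_idx, best_score
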