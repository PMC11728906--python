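"""Cavity-suture fiducial detection in en face planes.

The surgeon ties a short suture in the cavity at the suspicious region; it is
bright and elongated in OCT near the surface and is visible in both the
handheld (in vivo) and benchtop (ex vivo) en face images, anchoring the two
frames.  The detector is classical: top-hat filtering at the suture scale,
hysteresis thresholding, connected components, then gating on elongation and
physical width.  When several candidates pass (e.g. the long orientation
suture also lies in the field), the best-confidence one is returned with a
multiplicity flag and the caller disambiguates from the session notes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

from ._exceptions import InsufficientDataError
from .surface_enface import EnFacePlane

__all__ = ["FiducialMark", "detect_suture"]


@dataclass
class FiducialMark:
    """Detected suture: centroid and principal axis in physical plane coordinates."""

    centroid_um: tuple[float, float]  # (x, y)
    axis_deg: float  # principal orientation from +x, in (-90, 90]
    length_um: float
    width_um: float
    confidence: float  # in [0, 1]
    multiplicity: int = 1  # number of plausible candidates seen


def _principal_axis(coords_yx: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Weighted second-moment axis: returns (angle_deg from +x, length, width) in pixels.

    The angle convention is measured from the +x axis toward +y, wrapped to
    (-90, 90] (an undirected axis).
    """
    w = weights / weights.sum()
    y = coords_yx[:, 0].astype(float)
    x = coords_yx[:, 1].astype(float)
    my, mx = (w * y).sum(), (w * x).sum()
    yc, xc = y - my, x - mx
    mxx = (w * xc * xc).sum()
    myy = (w * yc * yc).sum()
    mxy = (w * xc * yc).sum()
    angle = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    common = math.hypot(mxx - myy, 2.0 * mxy)
    lam1 = 0.5 * (mxx + myy + common)
    lam2 = 0.5 * (mxx + myy - common)
    # 4-sigma axis lengths, the usual ellipse-equivalent convention
    length = 4.0 * math.sqrt(max(lam1, 0.0))
    width = 4.0 * math.sqrt(max(lam2, 0.0))
    deg = math.degrees(angle)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return deg, length, width


def detect_suture(
    plane: EnFacePlane,
    expected_width_um: tuple[float, float] = (100.0, 600.0),
    min_elongation: float = 3.0,
) -> FiducialMark | None:
    """Detect the cavity suture in an en face plane.

    Returns ``None`` when no bright connected component passes the elongation
    (length/width >= ``min_elongation``) and width gates.

    Raises
    ------
    InsufficientDataError
        If less than half the plane carries valid data.
    """
    if plane.valid_fraction < 0.5:
        raise InsufficientDataError(
            f"only {plane.valid_fraction:.0%} of the plane is valid; need >= 50%"
        )
    sp = 0.5 * (plane.spacing_y_um + plane.spacing_x_um)
    img = np.where(plane.valid, plane.image, np.nan)
    bg = float(np.nanmedian(img))
    img = np.where(np.isfinite(img), img, bg)

    # top-hat at suture scale: structuring element slightly wider than the widest
    # expected suture so ridges survive while broad tissue contrast is removed
    radius_px = max(2, int(round(0.75 * expected_width_um[1] / sp)))
    tophat = morphology.white_tophat(img, morphology.disk(radius_px))
    peak = float(tophat.max())
    if peak <= 0:
        return None
    high = 0.5 * peak
    low = 0.25 * peak
    mask = filters.apply_hysteresis_threshold(tophat, low, high)
    mask &= plane.valid
    labels = measure.label(mask)

    candidates = []
    mean_bg = max(bg, 0.0)
    for region in measure.regionprops(labels):
        if region.area < 5:
            continue
        coords = region.coords
        weights = np.clip(tophat[coords[:, 0], coords[:, 1]], 0, None) + 1e-12
        axis_deg, length_px, width_px = _principal_axis(coords, weights)
        length_um = length_px * sp
        width_um = max(width_px * sp, sp)
        if width_um < expected_width_um[0] or width_um > expected_width_um[1]:
            continue
        if length_um / width_um < min_elongation:
            continue
        yc, xc = np.average(coords[:, 0], weights=weights), np.average(coords[:, 1], weights=weights)
        mean_comp = float(img[coords[:, 0], coords[:, 1]].mean())
        confidence = float(np.clip((mean_comp - mean_bg) / (mean_comp + mean_bg + 1e-12), 0.0, 1.0))
        candidates.append(
            FiducialMark(
                centroid_um=(xc * plane.spacing_x_um, yc * plane.spacing_y_um),
                axis_deg=axis_deg,
                length_um=length_um,
                width_um=width_um,
                confidence=confidence,
            )
        )
    if not candidates:
        return None
    candidates.sort(key=lambda m: m.confidence, reverse=True)
    best = candidates[0]
    best.multiplicity = len(candidates)
    return best
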