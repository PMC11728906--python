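"""Placement of handheld (in vivo) tiles into the wide-field (ex vivo) frame.

The clinical procedure anchors the first tile at the cavity suture, coarsely
positions the remaining tiles from the 3x3 grid recorded during surgery, and
refines each placement by comparing tissue features between surface-flattened
en face planes, scrolling through depths to compensate probe pressure/tilt.
This module automates that workflow:

* :func:`coarse_place` — suture-anchored grid prior;
* :func:`refine_tile` — exhaustive rigid search (translation, yaw, depth
  plane) maximizing masked normalized cross-correlation on dB-scaled en face
  planes, with sub-grid quadratic refinement of translation;
* :func:`classify_tissue` — the 90% field-of-view rule labelling a tile
  dense / adipose / mixed;
* :func:`assess_success` — an automated surrogate for inter-rater agreement:
  a correlation-score gate plus a grid-consistency gate against already
  placed neighbours (adjacent tiles share ~1 mm of overlap);
* :func:`summarize` — the per-tissue-type success table.

Masked NCC is used because the two OCT systems differ in resolution and
intensity scale; normalized correlation is invariant to affine intensity
rescaling, and the masks exclude no-data pixels from both planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from ._exceptions import InsufficientDataError, ValidationError
from .fiducial import FiducialMark
from .phantom import RigidPose2D  # canonical pose type
from .surface_enface import EnFacePlane, detect_surface, extract_enface
from .volume_io import OCTVolume, ScanSession, to_decibels

__all__ = [
    "RigidPose2D",
    "SearchParams",
    "MosaicPlacement",
    "coarse_place",
    "refine_tile",
    "classify_tissue",
    "assess_success",
    "grid_consistency",
    "summarize",
    "summarize_counts",
    "masked_ncc_map",
    "register_session",
]

DEFAULT_SCORE_THRESHOLD = 0.3
DEFAULT_CONSISTENCY_THRESHOLD_UM = 1500.0


@dataclass(frozen=True)
class SearchParams:
    """Rigid search ranges for :func:`refine_tile`."""

    trans_um: float = 2000.0
    theta_deg: float = 10.0
    theta_step_deg: float = 0.5
    dz_um: float = 200.0
    dz_step_vox: int = 2
    min_overlap_fraction: float = 0.25
    #: lateral Gaussian smoothing (in wide-field pixels) applied to both dB
    #: planes before correlation; tames speckle noise in the score landscape
    smooth_px: float = 1.0


@dataclass
class MosaicPlacement:
    """Result of placing one tile in the wide-field frame."""

    tile_id: str
    pose: RigidPose2D
    score: float
    success: bool
    tissue_class: str  # dense | adipose | mixed
    overlap_consistency_um: float | None = None
    note_flags: tuple = ()


# ---------------------------------------------------------------------------
# Coarse placement from the session grid
# ---------------------------------------------------------------------------

def coarse_place(
    session: ScanSession,
    anchor_in_vivo: FiducialMark,
    anchor_ex_vivo: FiducialMark,
    tile_extent_um: float = 6000.0,
) -> dict:
    """Initial pose per tile: suture-anchored, grid-offset placement.

    The anchor tile's pose maps its detected suture centroid onto the ex vivo
    suture centroid, with initial yaw equal to the signed difference of the
    two suture axes.  Every other tile is offset from the anchor by
    ``(d_col, d_row) * nominal_step`` in the anchor's rotated frame; depth
    offsets start at zero.
    """
    if anchor_in_vivo is None or anchor_ex_vivo is None:
        raise ValidationError("both fiducial detections are required for coarse placement")
    theta = anchor_ex_vivo.axis_deg - anchor_in_vivo.axis_deg
    # axes are undirected (mod 180); take the smaller equivalent rotation
    theta = (theta + 90.0) % 180.0 - 90.0
    R = RigidPose2D(0, 0, theta).rotation()

    # vector from the in vivo tile centre to its suture, rotated into the
    # wide-field frame, fixes the anchor tile centre
    centre = np.array([tile_extent_um / 2, tile_extent_um / 2])
    p_local = np.array(anchor_in_vivo.centroid_um) - centre
    anchor_centre = np.array(anchor_ex_vivo.centroid_um) - R @ p_local

    anchor_rec = session.anchor
    poses = {}
    step = session.nominal_step_um
    for rec in session.tiles:
        d_col = rec.grid_col - anchor_rec.grid_col
        d_row = rec.grid_row - anchor_rec.grid_row
        offset = R @ np.array([d_col * step, d_row * step])
        poses[rec.tile_id] = RigidPose2D(
            tx_um=float(anchor_centre[0] + offset[0]),
            ty_um=float(anchor_centre[1] + offset[1]),
            theta_deg=float(theta),
            dz_um=0.0,
        )
    return poses


# ---------------------------------------------------------------------------
# Masked normalized cross-correlation (FFT, Padfield-style)
# ---------------------------------------------------------------------------

def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full cross-correlation: out[s] = sum_u a[u + s] b[u] (s from -(Hb-1))."""
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def masked_ncc_map(
    fixed: np.ndarray,
    fixed_mask: np.ndarray,
    moving: np.ndarray,
    moving_mask: np.ndarray,
    min_overlap: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of two masked images for every translation.

    Returns ``(ncc, n)`` in "full" correlation layout: index ``(i, j)``
    corresponds to placing the moving image's top-left corner at
    ``(i - Hm + 1, j - Wm + 1)`` in fixed-image coordinates.  Only pixels
    valid in both images contribute; shifts with fewer than ``min_overlap``
    overlapping pixels get NCC ``NaN``.
    """
    mf = fixed_mask.astype(np.float64)
    mm = moving_mask.astype(np.float64)
    f = np.where(fixed_mask, fixed, 0.0).astype(np.float64)
    t = np.where(moving_mask, moving, 0.0).astype(np.float64)

    n = _corr(mf, mm)
    sf = _corr(f, mm)
    st = _corr(mf, t)
    sft = _corr(f, t)
    sff = _corr(f * f, mm)
    stt = _corr(mf, t * t)

    n = np.round(n)
    ok = n >= max(min_overlap, 1)
    n_safe = np.where(ok, n, 1.0)
    cov = sft - sf * st / n_safe
    vf = sff - sf * sf / n_safe
    vt = stt - st * st / n_safe
    denom = np.sqrt(np.clip(vf, 0, None) * np.clip(vt, 0, None))
    ncc = np.where(ok & (denom > 1e-9), cov / np.maximum(denom, 1e-9), np.nan)
    ncc = np.clip(ncc, -1.0, 1.0)
    return ncc, n


def _masked_smooth(img: np.ndarray, mask: np.ndarray, sigma_px: float):
    """Gaussian smoothing that does not bleed no-data values into the image."""
    if sigma_px <= 0:
        return img
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(np.where(mask, img, 0.0), sigma_px, mode="nearest")
    den = ndimage.gaussian_filter(m, sigma_px, mode="nearest")
    return np.where(mask & (den > 1e-6), num / np.maximum(den, 1e-6), 0.0)


def _rotate_plane(img: np.ndarray, mask: np.ndarray, theta_deg: float):
    """Rotate a masked en face image by the world yaw angle ``theta_deg``.

    World convention: +theta rotates the +x axis toward +y (rows), which is
    the opposite sense of ``ndimage.rotate``'s positive angle, hence the
    negation.
    """
    if theta_deg == 0.0:
        return img, mask
    r = ndimage.rotate(np.where(mask, img, 0.0), -theta_deg, reshape=True, order=1, mode="constant", cval=0.0)
    rm = ndimage.rotate(mask.astype(np.float64), -theta_deg, reshape=True, order=1, mode="constant", cval=0.0)
    return r, rm > 0.5


def refine_tile(
    tile: OCTVolume,
    wide_field: OCTVolume,
    init: RigidPose2D,
    search: SearchParams = SearchParams(),
    depth_offset_um: float = 100.0,
    wf_plane: EnFacePlane | None = None,
) -> tuple[RigidPose2D, float]:
    """Refine a tile's rigid pose by exhaustive masked-NCC search.

    The tile's surface-flattened en face plane (at ``depth_offset_um + dz``)
    is compared, in dB, against the wide-field en face plane over a grid of
    yaw angles, depth offsets and translations around ``init``; the best
    translation is then refined below the grid spacing by a local quadratic
    fit.  Equal scores break toward the smallest |yaw|, then smallest |dz|,
    then smallest displacement from the initial pose.

    Returns ``(pose, score)``; if no candidate achieves the minimum valid
    overlap the tile is unregistrable and ``(init, -1.0)`` is returned.
    """
    sp_x, sp_y = wide_field.spacing_x_um, wide_field.spacing_y_um
    if wf_plane is None:
        wf_plane = extract_enface(wide_field, detect_surface(wide_field), depth_offset_um)
    wf_db = to_decibels(wf_plane.image)
    wf_mask = wf_plane.valid & np.isfinite(wf_db)
    wf_db = _masked_smooth(np.where(wf_mask, wf_db, 0.0), wf_mask, search.smooth_px)

    tile_surface = detect_surface(tile)
    tile_extent_x = tile.shape[2] * tile.spacing_x_um
    tile_extent_y = tile.shape[1] * tile.spacing_y_um

    # crop the wide-field plane around the initial footprint plus search margin
    half_diag = 0.5 * math.hypot(tile_extent_x, tile_extent_y)
    margin = half_diag + search.trans_um + 2 * max(sp_x, sp_y)
    x_lo = max(0, int((init.tx_um - margin) / sp_x))
    x_hi = min(wf_db.shape[1], int(math.ceil((init.tx_um + margin) / sp_x)))
    y_lo = max(0, int((init.ty_um - margin) / sp_y))
    y_hi = min(wf_db.shape[0], int(math.ceil((init.ty_um + margin) / sp_y)))
    if x_hi - x_lo < 4 or y_hi - y_lo < 4:
        return init, -1.0
    crop = wf_db[y_lo:y_hi, x_lo:x_hi]
    crop_mask = wf_mask[y_lo:y_hi, x_lo:x_hi]

    # depth-plane grid
    dz_step_um = max(search.dz_step_vox, 1) * tile.spacing_z_um
    if search.dz_um > 0:
        n_dz = int(search.dz_um / dz_step_um)
        dz_values = np.arange(-n_dz, n_dz + 1) * dz_step_um
    else:
        dz_values = np.array([0.0])
    dz_values = dz_values[dz_values + depth_offset_um >= 0]
    if search.theta_deg > 0:
        n_th = int(round(search.theta_deg / search.theta_step_deg))
        theta_values = init.theta_deg + np.arange(-n_th, n_th + 1) * search.theta_step_deg
    else:
        theta_values = np.array([init.theta_deg])

    needs_resample = abs(tile.spacing_x_um - sp_x) > 1e-9 or abs(tile.spacing_y_um - sp_y) > 1e-9

    best = None  # (key, pose, score)
    theta_scores: dict = {}  # (dz, theta) -> best score, for sub-grid yaw refinement
    for dz in dz_values:
        plane = extract_enface(tile, tile_surface, depth_offset_um + dz)
        t_db = to_decibels(plane.image)
        t_mask = plane.valid & np.isfinite(t_db)
        if not t_mask.any():
            continue
        t_db = _masked_smooth(np.where(t_mask, t_db, 0.0), t_mask, search.smooth_px * sp_x / tile.spacing_x_um)
        if needs_resample:
            fy = tile.spacing_y_um / sp_y
            fx = tile.spacing_x_um / sp_x
            t_db = ndimage.zoom(t_db, (fy, fx), order=1)
            t_mask = ndimage.zoom(t_mask.astype(np.float64), (fy, fx), order=1) > 0.5
        min_overlap = int(search.min_overlap_fraction * t_mask.sum())
        for theta in theta_values:
            r_img, r_mask = _rotate_plane(t_db, t_mask, theta)
            if not r_mask.any():
                continue
            ncc, n = masked_ncc_map(crop, crop_mask, r_img, r_mask, min_overlap=max(min_overlap, 16))
            hm, wm = r_img.shape
            # tile-centre world position for each shift in the full-correlation layout
            iy = np.arange(ncc.shape[0]) - (hm - 1)
            ix = np.arange(ncc.shape[1]) - (wm - 1)
            cx = (x_lo + ix + (wm - 1) / 2 + 0.5) * sp_x
            cy = (y_lo + iy + (hm - 1) / 2 + 0.5) * sp_y
            within = (np.abs(cy[:, None] - init.ty_um) <= search.trans_um) & (
                np.abs(cx[None, :] - init.tx_um) <= search.trans_um
            )
            cand = np.where(within & np.isfinite(ncc), ncc, -np.inf)
            if not np.isfinite(cand).any():
                continue
            flat = int(np.argmax(cand))
            py, px = np.unravel_index(flat, cand.shape)
            score = float(cand[py, px])
            # sub-grid quadratic refinement of translation
            dx_sub = dy_sub = 0.0
            if 0 < py < cand.shape[0] - 1:
                c0, cm, cp = cand[py, px], cand[py - 1, px], cand[py + 1, px]
                d = cm - 2 * c0 + cp
                if np.isfinite(cm) and np.isfinite(cp) and d < -1e-12:
                    dy_sub = float(np.clip(0.5 * (cm - cp) / d, -0.5, 0.5))
            if 0 < px < cand.shape[1] - 1:
                c0, cm, cp = cand[py, px], cand[py, px - 1], cand[py, px + 1]
                d = cm - 2 * c0 + cp
                if np.isfinite(cm) and np.isfinite(cp) and d < -1e-12:
                    dx_sub = float(np.clip(0.5 * (cm - cp) / d, -0.5, 0.5))
            tx = float(cx[px] + dx_sub * sp_x)
            ty = float(cy[py] + dy_sub * sp_y)
            dist = math.hypot(tx - init.tx_um, ty - init.ty_um)
            theta_scores[(float(dz), float(theta))] = score
            key = (-round(score, 9), abs(theta), abs(dz), dist)
            if best is None or key < best[0]:
                pose = RigidPose2D(tx_um=tx, ty_um=ty, theta_deg=float(theta), dz_um=float(dz))
                best = (key, pose, score)

    if best is None:
        return init, -1.0
    pose, score = best[1], best[2]
    # sub-grid quadratic refinement of yaw from the neighbouring grid angles
    step = search.theta_step_deg
    sm = theta_scores.get((pose.dz_um, pose.theta_deg - step))
    sp = theta_scores.get((pose.dz_um, pose.theta_deg + step))
    if sm is not None and sp is not None:
        d2 = sm - 2.0 * score + sp
        if d2 < -1e-12:
            d_theta = float(np.clip(0.5 * (sm - sp) / d2, -1.0, 1.0)) * step
            pose = RigidPose2D(pose.tx_um, pose.ty_um, pose.theta_deg + d_theta, pose.dz_um)
    return pose, score


# ---------------------------------------------------------------------------
# Tissue classification and success assessment
# ---------------------------------------------------------------------------

def classify_tissue(
    plane: EnFacePlane | None = None,
    class_map: np.ndarray | None = None,
    dense_db_offset: float = -6.0,
    window_um: float = 200.0,
    majority_fraction: float = 0.90,
) -> str:
    """Label a field of view dense / adipose / mixed by the 90% rule.

    A scan is "dense" (or "adipose") if more than ``majority_fraction`` of
    its field of view is that tissue type, else "mixed".  With a ground-truth
    ``class_map`` (0 = dense, 1 = adipose) the fractions are counted
    directly; otherwise per-pixel class is estimated from the local mean dB
    relative to the plane's bright level (adipose cell interiors backscatter
    weakly).
    """
    if class_map is not None:
        cm = np.asarray(class_map)
        if plane is not None and plane.valid.shape == cm.shape:
            sel = plane.valid
            if sel.mean() < 0.5:
                raise InsufficientDataError("less than half the plane is valid")
            cm = cm[sel]
        adipose_frac = float((cm == 1).mean())
        dense_frac = float((cm == 0).mean())
    else:
        if plane is None:
            raise ValidationError("need a plane or a class map")
        if plane.valid_fraction < 0.5:
            raise InsufficientDataError("less than half the plane is valid")
        db = to_decibels(plane.image)
        ok = plane.valid & np.isfinite(db)
        ref = np.percentile(db[ok], 99.0)
        size = (
            max(1, int(round(window_um / plane.spacing_y_um))),
            max(1, int(round(window_um / plane.spacing_x_um))),
        )
        local = ndimage.uniform_filter(np.where(ok, db, ref + dense_db_offset), size=size, mode="nearest")
        dense_px = local >= ref + dense_db_offset
        dense_frac = float(dense_px[ok].mean())
        adipose_frac = 1.0 - dense_frac
    if dense_frac > majority_fraction:
        return "dense"
    if adipose_frac > majority_fraction:
        return "adipose"
    return "mixed"


def assess_success(
    score: float,
    overlap_residual_um: float | None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    consistency_threshold_um: float = DEFAULT_CONSISTENCY_THRESHOLD_UM,
) -> bool:
    """Automated success surrogate: similarity gate AND grid-consistency gate.

    A placement succeeds if its correlation score clears the threshold and its
    mean residual against already-placed grid neighbours (which share ~1 mm
    of overlap by construction) stays within the consistency threshold.
    Tiles with no placed neighbours are judged on score alone.
    """
    if score < score_threshold:
        return False
    if overlap_residual_um is None:
        return True
    return overlap_residual_um <= consistency_threshold_um


def grid_consistency(session: ScanSession, poses: dict) -> dict:
    """Mean residual (um) of each tile's placement against its grid neighbours.

    For each pair of 4-adjacent placed tiles the expected relative offset is
    the grid delta times the nominal step, rotated by the pair's mean yaw;
    the residual is the norm of (realized - expected).  Tiles without placed
    neighbours map to ``None``.
    """
    recs = {r.tile_id: r for r in session.tiles}
    out = {}
    step = session.nominal_step_um
    for tid, rec in recs.items():
        if tid not in poses:
            continue
        residuals = []
        for oid, other in recs.items():
            if oid == tid or oid not in poses:
                continue
            d_row = other.grid_row - rec.grid_row
            d_col = other.grid_col - rec.grid_col
            if abs(d_row) + abs(d_col) != 1:
                continue
            pa, pb = poses[tid], poses[oid]
            theta = math.radians(0.5 * (pa.theta_deg + pb.theta_deg))
            c, s = math.cos(theta), math.sin(theta)
            ex = c * (d_col * step) - s * (d_row * step)
            ey = s * (d_col * step) + c * (d_row * step)
            rx = pb.tx_um - pa.tx_um
            ry = pb.ty_um - pa.ty_um
            residuals.append(math.hypot(rx - ex, ry - ey))
        out[tid] = float(np.mean(residuals)) if residuals else None
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _pct(num: float, den: float) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if den == 0:
        return 0
    return int(math.floor(100.0 * num / den + 0.5))


def summarize_counts(counts: dict) -> pd.DataFrame:
    """Success table from per-class (scanned, co-registered) counts.

    ``counts`` maps tissue type -> (n scanned, n co-registered).  The table
    reports, per class and in total, the number scanned (and its share of the
    data set) and the number co-registered (and its success rate), percentages
    rounded to the nearest integer.
    """
    if not counts:
        raise ValidationError("no counts to summarize")
    total_scanned = sum(v[0] for v in counts.values())
    total_cor = sum(v[1] for v in counts.values())
    if total_scanned == 0:
        raise ValidationError("zero scans in summary")
    rows = []
    for cls in ("dense", "adipose", "mixed"):
        if cls not in counts:
            continue
        n_s, n_c = counts[cls]
        if n_c > n_s:
            raise ValidationError(f"{cls}: co-registered ({n_c}) exceeds scanned ({n_s})")
        rows.append(
            {
                "tissue_type": cls,
                "n_scanned": n_s,
                "pct_of_total": _pct(n_s, total_scanned),
                "n_coregistered": n_c,
                "success_rate_pct": _pct(n_c, n_s),
            }
        )
    rows.append(
        {
            "tissue_type": "all",
            "n_scanned": total_scanned,
            "pct_of_total": 100,
            "n_coregistered": total_cor,
            "success_rate_pct": _pct(total_cor, total_scanned),
        }
    )
    return pd.DataFrame(rows)


def summarize(placements: list) -> pd.DataFrame:
    """Success table (per tissue class and total) from mosaic placements."""
    if not placements:
        raise ValidationError("no placements to summarize")
    counts = {}
    for p in placements:
        n_s, n_c = counts.get(p.tissue_class, (0, 0))
        counts[p.tissue_class] = (n_s + 1, n_c + int(p.success))
    return summarize_counts(counts)


# ---------------------------------------------------------------------------
# Session driver
# ---------------------------------------------------------------------------

def register_session(
    session: ScanSession,
    tile_volumes: dict,
    wide_field: OCTVolume,
    anchor_in_vivo: FiducialMark,
    anchor_ex_vivo: FiducialMark,
    search: SearchParams = SearchParams(),
    tile_classes: dict | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    consistency_threshold_um: float = DEFAULT_CONSISTENCY_THRESHOLD_UM,
    depth_offset_um: float = 100.0,
) -> list:
    """Place every session tile: coarse grid prior, per-tile refinement, gating.

    ``tile_volumes`` maps tile_id -> OCTVolume; ``tile_classes`` optionally
    maps tile_id -> ground-truth class label (otherwise the intensity rule is
    applied to each tile's en face plane).  Flagged tiles (poor contact,
    blood) are registered like any other and reported with their flags.
    """
    tile_extent = next(iter(tile_volumes.values())).shape[2] * next(iter(tile_volumes.values())).spacing_x_um
    init_poses = coarse_place(session, anchor_in_vivo, anchor_ex_vivo, tile_extent_um=tile_extent)
    wf_plane = extract_enface(wide_field, detect_surface(wide_field), depth_offset_um)

    refined, scores = {}, {}
    for rec in session.tiles:
        tid = rec.tile_id
        pose, score = refine_tile(
            tile_volumes[tid], wide_field, init_poses[tid], search=search,
            depth_offset_um=depth_offset_um, wf_plane=wf_plane,
        )
        refined[tid] = pose
        scores[tid] = score

    residuals = grid_consistency(session, refined)
    placements = []
    for rec in session.tiles:
        tid = rec.tile_id
        if tile_classes is not None and tid in tile_classes:
            cls = tile_classes[tid]
        else:
            plane = extract_enface(tile_volumes[tid], detect_surface(tile_volumes[tid]), depth_offset_um)
            cls = classify_tissue(plane)
        ok = assess_success(
            scores[tid], residuals.get(tid), score_threshold=score_threshold,
            consistency_threshold_um=consistency_threshold_um,
        )
        placements.append(
            MosaicPlacement(
                tile_id=tid,
                pose=refined[tid],
                score=scores[tid],
                success=ok,
                tissue_class=cls,
                overlap_consistency_um=residuals.get(tid),
                note_flags=tuple(sorted(rec.note_flags)),
            )
        )
    return placements
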