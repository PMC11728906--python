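"""Quantitative micro-elastography (QME): displacement, strain, stress, elasticity.

Compression elastography with a pre-characterized compliant layer: a
piezoelectric actuator applies a microscale axial displacement to the layer
and sample.  The local strain measured in the layer, mapped through the
layer's stress-strain curve, gives the local axial stress at the tissue
surface; stress is assumed uniaxial (constant along each A-line, a series of
springs).  Elasticity at each voxel is the ratio of that stress to the local
axial strain.

Displacement here is estimated by windowed 1-D cross-correlation of intensity
along depth with sub-voxel parabolic peak interpolation; strain is the slope
of a confidence-weighted least-squares line fit of displacement over a moving
axial window.  Axial displacement ``uz`` is positive toward greater depth and
decreases with depth under compression (fixed base), so compressive strain is
``-d(uz)/dz``; the high-level chain handles that sign so elasticity is
reported as a positive modulus in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.ndimage import uniform_filter, uniform_filter1d

from ._exceptions import ValidationError
from .volume_io import OCTVolume, StressStrainCurve, to_decibels

__all__ = [
    "DisplacementVolume",
    "ElasticityVolume",
    "estimate_displacement",
    "compute_strain",
    "layer_stress",
    "elasticity",
    "mask_invalid",
    "qme_chain",
    "STRAIN_NOISE_FLOOR",
]

#: Strains below this magnitude are treated as noise (voxel marked invalid).
STRAIN_NOISE_FLOOR = 1e-4


@dataclass
class DisplacementVolume:
    """Axial displacement field between the two compression states."""

    uz_um: np.ndarray  # (nz, ny, nx)
    confidence: np.ndarray  # (nz, ny, nx) correlation peak in [0, 1]
    spacing_z_um: float
    spacing_y_um: float
    spacing_x_um: float


@dataclass
class ElasticityVolume:
    """Per-voxel elasticity in kPa with a validity mask.

    Display on a log scale is a rendering convention only (``log_display``);
    all computation is in linear kPa.
    """

    E_kPa: np.ndarray
    valid: np.ndarray
    spacing_z_um: float
    spacing_y_um: float
    spacing_x_um: float
    log_display: bool = True


def estimate_displacement(
    pre: OCTVolume,
    post: OCTVolume,
    window_um: float = 150.0,
    max_shift_vox: int = 4,
    presmooth_vox: float = 0.0,
) -> DisplacementVolume:
    """Per-voxel axial shift between compression states by windowed 1-D correlation.

    For each voxel, the integer lag in ``[-max_shift_vox, max_shift_vox]``
    maximizing the windowed zero-mean normalized cross-correlation along
    depth is refined to sub-voxel precision by a Gaussian (log-parabolic)
    fit of the correlation peak — the standard particle-image-velocimetry
    trick that avoids the integer peak-locking bias a plain parabola shows
    on speckle.  Confidence is the peak correlation value.  ``presmooth_vox``
    optionally Gaussian-smooths both volumes axially before correlation.
    """
    if pre.shape != post.shape:
        raise ValidationError("pre/post volumes must share shape")
    if (pre.spacing_z_um, pre.spacing_y_um, pre.spacing_x_um) != (
        post.spacing_z_um,
        post.spacing_y_um,
        post.spacing_x_um,
    ):
        raise ValidationError("pre/post volumes must share spacings")
    nz = pre.nz
    w = max(3, int(round(window_um / pre.spacing_z_um)))
    w += 1 - w % 2
    if w > nz:
        raise ValidationError(f"correlation window ({w} voxels) exceeds volume depth ({nz})")

    a = np.asarray(pre.intensity, dtype=np.float64)
    a = np.where(np.isfinite(a), a, 0.0)
    b_full = np.asarray(post.intensity, dtype=np.float64)
    b_full = np.where(np.isfinite(b_full), b_full, 0.0)
    if presmooth_vox > 0:
        a = ndimage.gaussian_filter1d(a, presmooth_vox, axis=0, mode="nearest")
        b_full = ndimage.gaussian_filter1d(b_full, presmooth_vox, axis=0, mode="nearest")

    def _win(x):
        return uniform_filter1d(x, size=w, axis=0, mode="nearest")

    ma = _win(a)
    va = np.maximum(_win(a * a) - ma * ma, 0.0)
    lags = np.arange(-max_shift_vox, max_shift_vox + 1)
    ncc = np.empty((lags.size,) + a.shape, dtype=np.float64)
    for i, lag in enumerate(lags):
        # b_lag[z] = post[z + lag]; out-of-range depths repeat the edge value
        idx = np.clip(np.arange(nz) + lag, 0, nz - 1)
        b = b_full[idx]
        mb = _win(b)
        vb = np.maximum(_win(b * b) - mb * mb, 0.0)
        cov = _win(a * b) - ma * mb
        denom = np.sqrt(va * vb)
        ncc[i] = np.where(denom > 1e-20, cov / np.maximum(denom, 1e-20), 0.0)

    best = ncc.argmax(axis=0)
    peak = np.take_along_axis(ncc, best[None], axis=0)[0]
    interior = (best > 0) & (best < lags.size - 1)
    bm = np.take_along_axis(ncc, np.maximum(best - 1, 0)[None], axis=0)[0]
    bp = np.take_along_axis(ncc, np.minimum(best + 1, lags.size - 1)[None], axis=0)[0]
    # Gaussian (log-parabolic) peak fit where all three samples are positive,
    # plain parabola otherwise
    pos = interior & (bm > 1e-6) & (peak > 1e-6) & (bp > 1e-6)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.log(np.clip(bm, 1e-6, None))
        l0 = np.log(np.clip(peak, 1e-6, None))
        lp = np.log(np.clip(bp, 1e-6, None))
    dlog = lm - 2.0 * l0 + lp
    delta_log = np.where(pos & (dlog < -1e-12), 0.5 * (lm - lp) / np.where(dlog == 0, 1, dlog), 0.0)
    dlin = bm - 2.0 * peak + bp
    delta_lin = np.where(interior & (dlin < -1e-12), 0.5 * (bm - bp) / np.where(dlin == 0, 1, dlin), 0.0)
    delta = np.clip(np.where(pos, delta_log, delta_lin), -1.0, 1.0)
    # a perfect peak (identical windows) needs no refinement; the log fit is
    # ill-conditioned there because the neighbours are also near unity
    delta = np.where(peak >= 1.0 - 1e-9, 0.0, delta)
    uz = (lags[best] + delta) * pre.spacing_z_um
    return DisplacementVolume(
        uz_um=uz,
        confidence=np.clip(peak, 0.0, 1.0),
        spacing_z_um=pre.spacing_z_um,
        spacing_y_um=pre.spacing_y_um,
        spacing_x_um=pre.spacing_x_um,
    )


def compute_strain(disp: DisplacementVolume, fit_window_um: float = 100.0) -> np.ndarray:
    """Axial strain as the slope of a weighted least-squares line fit of uz vs depth.

    The fit runs over a centred moving window along depth with the correlation
    confidence as weights.  Voxels whose window carries (near-)zero total
    weight are NaN (invalid).
    """
    nz = disp.uz_um.shape[0]
    m = max(3, int(round(fit_window_um / disp.spacing_z_um)))
    m += 1 - m % 2
    if m > nz:
        raise ValidationError(f"fit window ({m} voxels) exceeds volume depth ({nz})")
    z = (np.arange(nz, dtype=np.float64) * disp.spacing_z_um)[:, None, None]
    u = np.asarray(disp.uz_um, dtype=np.float64)
    wgt = np.clip(np.asarray(disp.confidence, dtype=np.float64), 0.0, None)
    u0 = np.where(np.isfinite(u), u, 0.0)
    wgt = np.where(np.isfinite(u), wgt, 0.0)

    def _win(x):
        return uniform_filter1d(x, size=m, axis=0, mode="nearest")

    sw = _win(wgt * np.ones_like(u0))
    swz = _win(wgt * z)
    swu = _win(wgt * u0)
    swzz = _win(wgt * z * z)
    swzu = _win(wgt * z * u0)
    denom = swzz * sw - swz * swz
    num = swzu * sw - swz * swu
    ok = (sw > 1e-12) & (denom > 1e-12)
    strain = np.where(ok, num / np.where(ok, denom, 1.0), np.nan)
    return strain


def layer_stress(layer_strain, curve: StressStrainCurve, extrapolate: bool = False) -> np.ndarray:
    """Map measured layer strain to surface stress (kPa) through the layer curve.

    Monotone piecewise-linear interpolation; strains outside the characterized
    range raise unless ``extrapolate`` is enabled.
    """
    return np.asarray(curve.stress_at(np.asarray(layer_strain, dtype=float), extrapolate=extrapolate))


def elasticity(
    stress_kPa,
    strain,
    spacing_z_um: float = 1.0,
    spacing_y_um: float = 1.0,
    spacing_x_um: float = 1.0,
    strain_floor: float = STRAIN_NOISE_FLOOR,
) -> ElasticityVolume:
    """Per-voxel elasticity E = stress / strain (uniaxial model).

    ``stress_kPa`` is a lateral (y, x) map broadcast along depth; ``strain``
    is the (compressive-positive) strain volume.  Voxels with |strain| below
    the noise floor, non-finite strain, or non-positive resulting modulus are
    marked invalid rather than raising.
    """
    stress = np.asarray(stress_kPa, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if stress.ndim == 2:
        stress = stress[None]
    if stress.shape[1:] != eps.shape[1:]:
        raise ValidationError("stress map lateral shape does not match strain volume")
    valid = np.isfinite(eps) & (np.abs(eps) >= strain_floor) & np.isfinite(stress) & (stress > 0)
    safe = np.where(valid, eps, 1.0)
    E = np.where(valid, stress / safe, np.nan)
    valid = valid & np.isfinite(E) & (E > 0)
    E = np.where(valid, E, np.nan)
    return ElasticityVolume(
        E_kPa=E,
        valid=valid,
        spacing_z_um=spacing_z_um,
        spacing_y_um=spacing_y_um,
        spacing_x_um=spacing_x_um,
    )


def mask_invalid(
    E: ElasticityVolume,
    oct_vol: OCTVolume,
    adipose_db_threshold: float = -2.0,
    texture_db_threshold: float = 0.8,
    adipose_window_um: float = 200.0,
    stat_depth_um: float = 500.0,
    layer_strain=None,
    contact_strain_floor: float = STRAIN_NOISE_FLOOR,
) -> ElasticityVolume:
    """Mask elasticity artifacts in adipose and non-contact regions.

    Adipose tissue backscatters weakly, which corrupts displacement tracking
    and produces elasticity artifacts.  The segmentation is lateral, like the
    clinical workflow: each A-line is summarized by its median dB over the
    shallow tissue band, then pooled laterally over ``adipose_window_um``
    (at least an adipose cell diameter).  A column is masked as adipose when
    its pooled mean, referenced to the bright (dense) end of the lateral
    distribution, falls below ``adipose_db_threshold`` *and* the honeycomb
    texture is confirmed: the lateral standard deviation of the column
    statistic exceeds ``texture_db_threshold`` (dark cell interiors against
    bright septa; plain dense speckle averages out far smoother).  Columns
    where the layer strain magnitude is below ``contact_strain_floor`` carry
    no load (non-contact) and are likewise masked.  The rules are monotone:
    loosening a threshold never unmasks voxels.
    """
    if E.E_kPa.shape != oct_vol.shape:
        raise ValidationError("elasticity and OCT volumes must be co-registered (same shape)")
    db = to_decibels(oct_vol)
    # restrict to depths carrying elasticity estimates (this skips the
    # compliant layer, which looks identical over every column) and to the
    # shallow tissue band: at depth, differential attenuation makes dense
    # tissue as dark as adipose and the intensity contrast inverts
    zsel = E.valid.any(axis=(1, 2))
    if zsel.any():
        z0 = int(np.argmax(zsel))
        n_stat = max(3, int(round(stat_depth_um / oct_vol.spacing_z_um)))
        zsel[z0 + n_stat :] = False
    col_db = np.nanmedian(db[zsel] if zsel.any() else db, axis=0)
    # lateral pooling over at least an adipose cell diameter, so bright septum
    # columns are averaged with the dark cell interiors around them; the same
    # window's standard deviation is the honeycomb-texture statistic
    ky = max(1, int(round(adipose_window_um / oct_vol.spacing_y_um)))
    kx = max(1, int(round(adipose_window_um / oct_vol.spacing_x_um)))
    ky += 1 - ky % 2
    kx += 1 - kx % 2
    m1 = ndimage.uniform_filter(col_db, size=(ky, kx), mode="nearest")
    m2 = ndimage.uniform_filter(col_db * col_db, size=(ky, kx), mode="nearest")
    texture = np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))
    # reference: the bright (dense) end of the column-statistic distribution,
    # so the threshold is relative and robust to overall intensity scale
    ref = np.nanpercentile(m1, 90.0)
    adipose_col = (m1 - ref < adipose_db_threshold) & (texture > texture_db_threshold)
    keep_col = ~adipose_col
    if layer_strain is not None:
        keep_col &= np.abs(np.asarray(layer_strain, dtype=float)) >= contact_strain_floor
    new_valid = E.valid & keep_col[None]
    return replace(E, E_kPa=np.where(new_valid, E.E_kPa, np.nan), valid=new_valid)


def qme_chain(
    pre: OCTVolume,
    post: OCTVolume,
    curve: StressStrainCurve,
    layer_thickness_um: float,
    window_um: float = 150.0,
    fit_window_um: float = 150.0,
    max_shift_vox: int = 4,
    mask: bool = True,
    extrapolate_layer: bool = True,
) -> tuple[ElasticityVolume, dict]:
    """Full QME pipeline: displacement -> strain -> layer stress -> elasticity.

    The layer occupies the top ``layer_thickness_um`` of the volumes; its
    median compressive strain per lateral position (measured from the same
    displacement field) is mapped through the layer curve to the stress used
    for the whole A-line.  Returns the (optionally masked) elasticity volume
    and a dict of intermediate fields for inspection.
    """
    disp = estimate_displacement(pre, post, window_um=window_um, max_shift_vox=max_shift_vox)
    strain_raw = compute_strain(disp, fit_window_um=fit_window_um)
    comp = -strain_raw  # compressive-positive
    n_layer = int(round(layer_thickness_um / pre.spacing_z_um))
    if n_layer < 3:
        raise ValidationError("layer thinner than 3 voxels; cannot measure layer strain")
    # layer strain: direct per-column line fit of displacement across the layer,
    # keeping half a correlation window clear of the top edge (padding bias)
    # and of the layer/tissue boundary (bright tissue entering the window)
    w_corr = max(3, int(round(window_um / pre.spacing_z_um)))
    lo = min(max(2, w_corr // 2 + 1), max(n_layer - 4, 2))
    hi = max(n_layer - w_corr // 2 - 2, lo + 3)
    z_um = np.arange(lo, hi) * pre.spacing_z_um
    slope = np.polyfit(z_um, disp.uz_um[lo:hi].reshape(hi - lo, -1), 1)[0]
    layer_eps = np.clip(-slope.reshape(disp.uz_um.shape[1:]), 0.0, None)
    stress = layer_stress(layer_eps, curve, extrapolate=extrapolate_layer)
    E = elasticity(
        stress,
        comp,
        spacing_z_um=pre.spacing_z_um,
        spacing_y_um=pre.spacing_y_um,
        spacing_x_um=pre.spacing_x_um,
    )
    # the layer itself is not tissue: mask it out of the elasticity map
    E.valid[:n_layer] = False
    E.E_kPa[:n_layer] = np.nan
    if mask:
        E = mask_invalid(E, pre, layer_strain=layer_eps)
    extras = {
        "displacement": disp,
        "strain": comp,
        "layer_strain": layer_eps,
        "stress_kPa": stress,
    }
    return E, extras
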