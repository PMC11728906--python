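"""Synthetic cavity-shaving phantoms with full ground truth.

The generator emulates the image appearance of wide-field OCT of an excised
breast cavity shaving well enough to exercise every pipeline stage without
clinical data:

* dense stroma: high, smoothly varying backscatter that attenuates
  exponentially with depth below the surface;
* adipose tissue: the characteristic honeycomb — dark cell interiors with
  bright septa, rendered from a Voronoi-like nearest-seed partition with cell
  diameters of 60-120 um;
* a suture fiducial: a bright elongated ridge that protrudes above the tissue
  surface;
* tubular features (vessels/nerves): dark lumens with bright walls running
  parallel to the surface;
* fully developed speckle: multiplicative exponential-intensity noise on the
  smooth reflectivity map, lightly blurred to emulate the system PSF;
* smooth random surface topography.

Alongside the intensity volume the generator returns per-pixel ground truth
(tissue class, suture geometry, elasticity, surface depth) so detection and
registration accuracy can be measured, plus forward models for the
compression (elastography) pair and shrunken/warped histology sections.
All randomness flows from a single seed: the same spec yields a bit-identical
phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._exceptions import ValidationError
from .histology_map import HistologySection
from .volume_io import OCTVolume, StressStrainCurve

__all__ = [
    "PhantomSpec",
    "SutureSpec",
    "TubularFeature",
    "GroundTruth",
    "Degrade",
    "CompressionTruth",
    "generate_shaving_phantom",
    "extract_tile",
    "simulate_compression_pair",
    "generate_histology_sections",
    "RigidPose2D",
]


@dataclass(frozen=True)
class RigidPose2D:
    """Lateral rigid pose of a tile relative to the wide-field frame.

    ``tx_um, ty_um`` place the tile centre; ``theta_deg`` is the in-plane
    (yaw) rotation in (-180, 180]; ``dz_um`` is a depth-offset adjustment of
    the en face sampling plane (the automated analogue of scrolling through
    depths when the probe was tilted or pressed differently).
    """

    tx_um: float
    ty_um: float
    theta_deg: float = 0.0
    dz_um: float = 0.0

    def __post_init__(self):
        if not (-180.0 < self.theta_deg <= 180.0):
            raise ValidationError(f"theta_deg must be in (-180, 180], got {self.theta_deg}")

    def rotation(self) -> np.ndarray:
        t = math.radians(self.theta_deg)
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class SutureSpec:
    """Geometry of the rendered cavity-suture ridge."""

    present: bool = True
    centroid_um: tuple[float, float] | None = None  # (x, y); None = field centre
    length_um: float = 3000.0
    width_um: float = 300.0
    axis_deg: float = 0.0
    protrusion_um: float = 100.0


@dataclass(frozen=True)
class TubularFeature:
    """A vessel or nerve: a tube parallel to the surface at a fixed depth."""

    kind: str  # "vessel" | "nerve"
    start_um: tuple[float, float]  # (x, y)
    end_um: tuple[float, float]
    depth_um: float = 400.0
    radius_um: float = 150.0
    wall_intensity: float = 1.0
    lumen_intensity: float = 0.02


@dataclass
class PhantomSpec:
    """Parameters of a synthetic shaving phantom.

    Defaults approximate the study geometry: lateral spacing 12.7 um and axial
    spacing 3.4 um (the printed field-of-view over pixel-count ratios) over a
    20 x 20 x 3.5 mm^3 specimen.  Tests and demos use smaller extents and
    coarser spacings; the appearance model is scale-aware (cell sizes and
    feature geometry are specified in micrometres).
    """

    extent_um: tuple[float, float, float] = (20000.0, 20000.0, 3500.0)  # (x, y, z)
    spacing_lateral_um: float = 12.7
    spacing_axial_um: float = 3.4
    adipose_fraction: float = 0.3
    features: tuple = ()
    suture: SutureSpec = field(default_factory=SutureSpec)
    attenuation_per_mm: float = 2.0  # dense-tissue linear attenuation (1/mm)
    speckle_contrast: float = 0.7
    surface_topography_amplitude_um: float = 80.0
    seed: int = 0
    # secondary appearance/mechanics parameters
    base_surface_depth_um: float = 120.0
    adipose_cell_diameter_um: tuple[float, float] = (60.0, 120.0)
    class_blob_size_um: float = 1500.0
    dense_texture_scale_um: float = 700.0
    thermal_fraction: float = 0.08
    elasticity_dense_kPa: float = 15.0
    elasticity_adipose_kPa: float = 3.0
    elasticity_thermal_kPa: float = 25.0

    def __post_init__(self):
        for name, v in (("adipose_fraction", self.adipose_fraction), ("thermal_fraction", self.thermal_fraction)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.spacing_lateral_um <= 0 or self.spacing_axial_um <= 0:
            raise ValidationError("spacings must be positive")
        ex, ey, ez = self.extent_um
        if min(ex, ey, ez) <= 0:
            raise ValidationError("extent must be positive")
        if self.suture.present:
            cx, cy = self.suture.centroid_um if self.suture.centroid_um is not None else (ex / 2, ey / 2)
            if not (0 <= cx <= ex and 0 <= cy <= ey):
                raise ValidationError(f"suture centroid ({cx}, {cy}) outside extent ({ex}, {ey})")
        for f in self.features:
            for px, py in (f.start_um, f.end_um):
                if not (0 <= px <= ex and 0 <= py <= ey):
                    raise ValidationError(f"feature endpoint ({px}, {py}) outside extent")
            if f.depth_um + f.radius_um > ez:
                raise ValidationError("feature deeper than the axial extent")

    @property
    def shape(self) -> tuple[int, int, int]:
        ex, ey, ez = self.extent_um
        return (
            int(round(ez / self.spacing_axial_um)),
            int(round(ey / self.spacing_lateral_um)),
            int(round(ex / self.spacing_lateral_um)),
        )

    def suture_centroid_um(self) -> tuple[float, float]:
        if self.suture.centroid_um is not None:
            return self.suture.centroid_um
        return (self.extent_um[0] / 2, self.extent_um[1] / 2)


@dataclass
class GroundTruth:
    """Per-pixel ground truth accompanying a generated phantom."""

    tissue_class: np.ndarray  # (ny, nx) uint8: 0 = dense, 1 = adipose
    feature_masks: dict  # name -> (nz, ny, nx) bool
    suture_mask: np.ndarray | None  # (ny, nx) bool footprint
    suture_centroid_um: tuple[float, float] | None  # (x, y)
    suture_axis_deg: float | None
    elasticity_map_kPa: np.ndarray  # (ny, nx) > 0
    surface_depth_um: np.ndarray  # (ny, nx)
    specimen_mask: np.ndarray  # (ny, nx) bool

    def __post_init__(self):
        if self.elasticity_map_kPa.shape != self.tissue_class.shape:
            raise ValidationError("elasticity map lateral shape mismatch")
        if np.any(self.elasticity_map_kPa <= 0):
            raise ValidationError("elasticity must be positive everywhere")


@dataclass(frozen=True)
class Degrade:
    """In vivo degradation knobs applied when extracting a handheld tile.

    ``noise_sigma`` is the std of additive intensity noise (phantom tissue is
    O(0.5)); ``blur_sigma_um`` a lateral Gaussian blur emulating the coarser
    handheld resolution; ``blood_opacity`` an attenuating surface film;
    ``tilt_deg`` a linear ramp of sampled depth across the tile (probe tilt);
    and ``warp_amplitude_um``/``warp_scale_um`` a smooth random lateral
    deformation emulating tissue distortion between acquisitions (probe
    pressure in the cavity vs. the benchtop mount), which decorrelates
    cell-scale detail while preserving larger structure.
    """

    noise_sigma: float = 0.0
    blur_sigma_um: float = 0.0
    blood_opacity: float = 0.0
    tilt_deg: float = 0.0
    warp_amplitude_um: float = 0.0
    warp_scale_um: float = 300.0


def _smooth_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_px, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def _honeycomb(rng: np.random.Generator, ny: int, nx: int, sp_um: float, dia_range) -> np.ndarray:
    """Voronoi-cell honeycomb reflectivity: bright septa, dark interiors."""
    d_mean = 0.5 * (dia_range[0] + dia_range[1])
    area_um2 = ny * nx * sp_um * sp_um
    n_cells = max(4, int(area_um2 / (0.25 * math.pi * d_mean**2)))
    seeds = rng.uniform([0, 0], [ny * sp_um, nx * sp_um], size=(n_cells, 2))
    yy, xx = np.meshgrid((np.arange(ny) + 0.5) * sp_um, (np.arange(nx) + 0.5) * sp_um, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dist, _ = cKDTree(seeds).query(pts, k=2)
    ridge = dist[:, 1] - dist[:, 0]  # ~0 on Voronoi boundaries
    septum_um = 5.0  # physical septum scale; sub-resolution at coarse spacing
    img = 0.03 + 0.77 * np.exp(-0.5 * (ridge.reshape(ny, nx) / septum_um) ** 2)
    return img


def _segment_distance_um(yy_um, xx_um, start_um, end_um):
    """Lateral distance from each pixel to a segment (inputs in um, (x, y) points)."""
    p = np.stack([xx_um, yy_um], axis=-1)
    a = np.array(start_um, dtype=float)
    b = np.array(end_um, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1)


def generate_shaving_phantom(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Render a wide-field shaving phantom and its ground truth.

    Deterministic: the same spec (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    sp = spec.spacing_lateral_um
    dz = spec.spacing_axial_um

    # --- lateral tissue-class map: smooth field thresholded at the target quantile
    blob_px = max(1.0, spec.class_blob_size_um / sp)
    g = _smooth_field(rng, (ny, nx), blob_px)
    if spec.adipose_fraction <= 0:
        adipose = np.zeros((ny, nx), dtype=bool)
    elif spec.adipose_fraction >= 1:
        adipose = np.ones((ny, nx), dtype=bool)
    else:
        q = np.quantile(g, 1.0 - spec.adipose_fraction)
        adipose = g > q
    tissue_class = adipose.astype(np.uint8)

    # --- lateral reflectivity
    dense_tex = 1.0 + 0.22 * _smooth_field(rng, (ny, nx), max(1.0, spec.dense_texture_scale_um / sp))
    dense_reflect = 0.7 * np.clip(dense_tex, 0.4, 1.6)
    honey = _honeycomb(rng, ny, nx, sp, spec.adipose_cell_diameter_um)
    reflect = np.where(adipose, honey, dense_reflect)

    # --- thermal-damage patches (within dense tissue) for the elasticity map
    th = _smooth_field(rng, (ny, nx), blob_px)
    if spec.thermal_fraction > 0:
        thermal = (th > np.quantile(th, 1.0 - spec.thermal_fraction)) & ~adipose
    else:
        thermal = np.zeros((ny, nx), dtype=bool)
    elasticity = np.where(
        adipose, spec.elasticity_adipose_kPa, np.where(thermal, spec.elasticity_thermal_kPa, spec.elasticity_dense_kPa)
    ).astype(np.float64)

    # --- surface topography
    topo = _smooth_field(rng, (ny, nx), max(1.0, 2000.0 / sp))
    surface_um = spec.base_surface_depth_um + spec.surface_topography_amplitude_um * topo
    min_depth = max(2 * dz, spec.suture.protrusion_um + 2 * dz)
    surface_um = np.clip(surface_um, min_depth, spec.extent_um[2] / 3)

    # --- suture ridge: raised surface + very bright footprint
    suture_mask = None
    suture_centroid = None
    suture_axis = None
    if spec.suture.present:
        cx, cy = spec.suture_centroid_um()
        suture_centroid = (cx, cy)
        suture_axis = spec.suture.axis_deg
        yy_um, xx_um = np.meshgrid((np.arange(ny) + 0.5) * sp, (np.arange(nx) + 0.5) * sp, indexing="ij")
        t = math.radians(spec.suture.axis_deg)
        u = (xx_um - cx) * math.cos(t) + (yy_um - cy) * math.sin(t)
        v = -(xx_um - cx) * math.sin(t) + (yy_um - cy) * math.cos(t)
        suture_mask = (np.abs(u) <= spec.suture.length_um / 2) & (np.abs(v) <= spec.suture.width_um / 2)
        surface_um = np.where(suture_mask, np.maximum(surface_um - spec.suture.protrusion_um, dz), surface_um)

    # --- assemble the volume
    z_um = (np.arange(nz, dtype=np.float64) + 0.5) * dz
    depth_below = z_um[:, None, None] - surface_um[None, :, :]
    mu_dense = spec.attenuation_per_mm / 1000.0  # per um
    mu = np.where(adipose, 0.3 * mu_dense, mu_dense)
    inside = depth_below >= 0
    atten = np.exp(-mu[None] * np.clip(depth_below, 0, None))
    vol = np.where(inside, reflect[None] * atten, 0.0)

    if suture_mask is not None:
        ridge = inside & suture_mask[None] & (depth_below <= spec.suture.protrusion_um + 200.0)
        vol = np.where(ridge, 1.5, vol)

    feature_masks: dict = {}
    if spec.features:
        yy_um, xx_um = np.meshgrid((np.arange(ny) + 0.5) * sp, (np.arange(nx) + 0.5) * sp, indexing="ij")
        for i, f in enumerate(spec.features):
            dl = _segment_distance_um(yy_um, xx_um, f.start_um, f.end_um)
            axis_z = surface_um + f.depth_um
            dv = z_um[:, None, None] - axis_z[None]
            r = np.sqrt(dl[None] ** 2 + dv**2)
            lumen = r < max(f.radius_um - 30.0, 0.4 * f.radius_um)
            tube = r < f.radius_um
            wall = tube & ~lumen
            vol = np.where(wall & inside, f.wall_intensity, vol)
            vol = np.where(lumen & inside, f.lumen_intensity, vol)
            feature_masks[f"{f.kind}_{i}"] = tube & inside

    # --- speckle and PSF blur
    s = spec.speckle_contrast
    if s > 0:
        speckle = rng.exponential(1.0, size=vol.shape)
        vol = vol * (1.0 - s + s * speckle)
    vol = ndimage.gaussian_filter(vol, sigma=0.75, mode="nearest")
    vol = np.clip(vol, 0.0, None).astype(np.float32)

    wide = OCTVolume(
        intensity=vol,
        spacing_z_um=dz,
        spacing_y_um=sp,
        spacing_x_um=sp,
        role="wide_field",
        tile_id="phantom",
    )
    truth = GroundTruth(
        tissue_class=tissue_class,
        feature_masks=feature_masks,
        suture_mask=suture_mask,
        suture_centroid_um=suture_centroid,
        suture_axis_deg=suture_axis,
        elasticity_map_kPa=elasticity,
        surface_depth_um=surface_um,
        specimen_mask=np.ones((ny, nx), dtype=bool),
    )
    return wide, truth


# ---------------------------------------------------------------------------
# Handheld-tile extraction
# ---------------------------------------------------------------------------

def extract_tile(
    wide_field: OCTVolume,
    truth: GroundTruth,
    pose: RigidPose2D,
    degrade: Degrade = Degrade(),
    tile_extent_um: float = 6000.0,
    tile_id: str | None = None,
    seed: int = 0,
) -> OCTVolume:
    """Cut a handheld (in vivo) tile out of the wide-field phantom at a rigid pose.

    With zero rotation, zero degradation and matched spacings the tile equals
    the corresponding wide-field crop voxel-for-voxel.  ``tilt_deg`` shears
    the sampled depth linearly across the tile's x axis, emulating probe tilt.

    Raises
    ------
    ValidationError
        If the tile footprint falls outside the wide-field extent.
    """
    rng = np.random.default_rng(seed)
    sp_x, sp_y, sp_z = wide_field.spacing_x_um, wide_field.spacing_y_um, wide_field.spacing_z_um
    nz, ny, nx = wide_field.shape
    n_lat_x = int(round(tile_extent_um / sp_x))
    n_lat_y = int(round(tile_extent_um / sp_y))

    # centred local physical coordinates, rotated into the wide-field frame
    xl = (np.arange(n_lat_x) + 0.5) * sp_x - tile_extent_um / 2
    yl = (np.arange(n_lat_y) + 0.5) * sp_y - tile_extent_um / 2
    YL, XL = np.meshgrid(yl, xl, indexing="ij")
    R = pose.rotation()
    XW = pose.tx_um + R[0, 0] * XL + R[0, 1] * YL
    YW = pose.ty_um + R[1, 0] * XL + R[1, 1] * YL

    ex, ey = nx * sp_x, ny * sp_y
    if XW.min() < -sp_x / 2 or XW.max() > ex + sp_x / 2 or YW.min() < -sp_y / 2 or YW.max() > ey + sp_y / 2:
        raise ValidationError("tile footprint outside the wide-field extent")

    if degrade.warp_amplitude_um > 0:
        # smooth elastic deformation of the sampled coordinates; edges clamp
        sig = max(1.0, degrade.warp_scale_um / sp_x)
        wx = ndimage.gaussian_filter(rng.standard_normal(XW.shape), sig, mode="reflect")
        wy = ndimage.gaussian_filter(rng.standard_normal(YW.shape), sig, mode="reflect")
        for w in (wx, wy):
            s = w.std()
            if s > 0:
                w /= s
        XW = XW + degrade.warp_amplitude_um * wx
        YW = YW + degrade.warp_amplitude_um * wy

    xp = XW / sp_x - 0.5  # pixel coordinates
    yp = YW / sp_y - 0.5
    data = np.where(np.isfinite(wide_field.intensity), wide_field.intensity, 0.0).astype(np.float64)

    if degrade.tilt_deg != 0.0:
        shear_um = math.tan(math.radians(degrade.tilt_deg)) * XL  # depth ramp across x
        zz = np.arange(nz, dtype=np.float64)[:, None, None] + (shear_um / sp_z)[None]
        coords = np.stack(
            [
                np.broadcast_to(zz, (nz, n_lat_y, n_lat_x)),
                np.broadcast_to(yp[None], (nz, n_lat_y, n_lat_x)),
                np.broadcast_to(xp[None], (nz, n_lat_y, n_lat_x)),
            ]
        )
        tile = ndimage.map_coordinates(data, coords.reshape(3, -1), order=1, mode="nearest").reshape(
            nz, n_lat_y, n_lat_x
        )
    else:
        tile = np.empty((nz, n_lat_y, n_lat_x), dtype=np.float64)
        flat = np.stack([yp.ravel(), xp.ravel()])
        for z in range(nz):
            tile[z] = ndimage.map_coordinates(data[z], flat, order=1, mode="nearest").reshape(n_lat_y, n_lat_x)

    if degrade.blur_sigma_um > 0:
        tile = ndimage.gaussian_filter(
            tile, sigma=(0.0, degrade.blur_sigma_um / sp_y, degrade.blur_sigma_um / sp_x), mode="nearest"
        )
    if degrade.blood_opacity > 0:
        surf = ndimage.map_coordinates(truth.surface_depth_um, np.stack([yp.ravel(), xp.ravel()]), order=1).reshape(
            n_lat_y, n_lat_x
        )
        z_um = (np.arange(nz) + 0.5) * sp_z
        below = z_um[:, None, None] >= surf[None]
        film = below & (z_um[:, None, None] < (surf + 40.0)[None])
        tile = np.where(below, tile * math.exp(-degrade.blood_opacity), tile)
        tile = np.where(film, tile + 0.8 * degrade.blood_opacity, tile)
    if degrade.noise_sigma > 0:
        tile = tile + degrade.noise_sigma * rng.standard_normal(tile.shape)
    tile = np.clip(tile, 0.0, None).astype(np.float32)

    return OCTVolume(
        intensity=tile,
        spacing_z_um=sp_z,
        spacing_y_um=sp_y,
        spacing_x_um=sp_x,
        role="in_vivo_tile",
        tile_id=tile_id,
        origin_um=(pose.tx_um - tile_extent_um / 2, pose.ty_um - tile_extent_um / 2),
    )


# ---------------------------------------------------------------------------
# Compression pair (forward model for QME)
# ---------------------------------------------------------------------------

@dataclass
class CompressionTruth:
    """Ground truth accompanying a simulated compression pair."""

    uz_um: np.ndarray  # (nz, ny, nx) axial displacement at pre-state coordinates
    strain: np.ndarray  # (nz, ny, nx) compressive strain
    layer_strain: np.ndarray  # (ny, nx)
    stress_kPa: np.ndarray  # (ny, nx)
    n_layer: int  # layer thickness in voxels


def simulate_compression_pair(
    wide_field: OCTVolume,
    truth: GroundTruth,
    layer: StressStrainCurve,
    layer_thickness_um: float = 500.0,
    actuation_um: float = 10.0,
    elasticity_3d: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[OCTVolume, OCTVolume, CompressionTruth]:
    """Simulate the actuated compression the elastography inversion assumes.

    The compliant layer (characterized by ``layer``) is stacked on top of the
    sample and the actuator face is displaced by ``actuation_um``; the base is
    fixed.  With uniaxial (series-spring) mechanics, stress is constant along
    each A-line, so per lateral position the stress solves

        actuation = eps_layer(sigma) * t_layer + sigma * sum_z dz / E(z).

    The post volume is the pre volume axially warped by the resulting
    displacement field.  ``elasticity_3d`` overrides the lateral ground-truth
    elasticity map with a full (nz, ny, nx) field (e.g. a two-layer sample).

    Raises
    ------
    ValidationError
        If the required layer strain falls outside the characterized curve.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = wide_field.shape
    dz = wide_field.spacing_z_um
    n_layer = int(round(layer_thickness_um / dz))
    if n_layer < 3:
        raise ValidationError("layer must span at least 3 voxels")
    t_layer = n_layer * dz

    if elasticity_3d is not None:
        E = np.asarray(elasticity_3d, dtype=np.float64)
        if E.shape != (nz, ny, nx):
            raise ValidationError("elasticity_3d must match the wide-field shape")
    else:
        E = np.broadcast_to(truth.elasticity_map_kPa[None], (nz, ny, nx)).astype(np.float64)
    if np.any(E <= 0):
        raise ValidationError("elasticity must be positive")

    # pre volume: speckled layer band stacked above the sample
    layer_band = 0.2 * (0.3 + 0.7 * rng.exponential(1.0, size=(n_layer, ny, nx)))
    layer_band = ndimage.gaussian_filter(layer_band, sigma=0.75, mode="nearest").astype(np.float64)
    sample = np.where(np.isfinite(wide_field.intensity), wide_field.intensity, 0.0).astype(np.float64)
    pre = np.concatenate([layer_band, sample], axis=0)
    # band-limit axially (the imaging PSF): sub-voxel warps are only meaningful
    # on speckle whose axial correlation length exceeds the voxel pitch
    pre = ndimage.gaussian_filter1d(pre, sigma=1.2, axis=0, mode="nearest")
    nz_tot = pre.shape[0]

    # solve the series-spring balance per lateral position
    compliance = (dz / E).sum(axis=0)  # um / kPa
    sig_grid = np.linspace(0.0, layer.stress_points_kPa[-1], 512)
    eps_grid = layer.strain_at(sig_grid)
    c_flat = compliance.ravel()
    sigma = np.empty_like(c_flat)
    for i, c in enumerate(c_flat):
        delta = eps_grid * t_layer + sig_grid * c
        if actuation_um > delta[-1]:
            raise ValidationError(
                "actuation drives the layer beyond its characterized strain range; "
                "reduce actuation_um or extend the curve"
            )
        sigma[i] = np.interp(actuation_um, delta, sig_grid)
    sigma = sigma.reshape(ny, nx)
    layer_eps = layer.strain_at(sigma)

    # displacement in the imaging (window) frame: the window at z = 0 is the
    # fixed reference, so material moves toward it with magnitude accumulating
    # with depth: u(z) = -integral_0^z strain dz', reaching -actuation at the base
    strain_sample = sigma[None] / E  # (nz, ny, nx) compressive
    strain_full = np.concatenate([np.broadcast_to(layer_eps[None], (n_layer, ny, nx)), strain_sample], axis=0)
    uz = -np.cumsum(strain_full, axis=0) * dz

    # axial warp: material at z0 appears at z0 + u(z0)/dz in the post volume
    z_idx = np.arange(nz_tot, dtype=np.float64)
    post = np.empty_like(pre)
    u_vox = uz / dz
    for iy in range(ny):
        for ix in range(nx):
            post[:, iy, ix] = np.interp(z_idx, z_idx + u_vox[:, iy, ix], pre[:, iy, ix])

    meta = dict(
        spacing_z_um=dz,
        spacing_y_um=wide_field.spacing_y_um,
        spacing_x_um=wide_field.spacing_x_um,
        role=wide_field.role,
    )
    pre_vol = OCTVolume(intensity=pre.astype(np.float32), tile_id="pre", **meta)
    post_vol = OCTVolume(intensity=post.astype(np.float32), tile_id="post", **meta)
    return pre_vol, post_vol, CompressionTruth(
        uz_um=uz, strain=strain_full, layer_strain=layer_eps, stress_kPa=sigma, n_layer=n_layer
    )


# ---------------------------------------------------------------------------
# Histology sections
# ---------------------------------------------------------------------------

def generate_histology_sections(
    wide_field: OCTVolume,
    truth: GroundTruth,
    section_spacing_um: float = 4500.0,
    shrink_factors=None,
    warp_amplitude_um: float = 0.0,
    seed: int = 0,
) -> list[HistologySection]:
    """Cut bread-loaf sections from the phantom with shrinkage and warping.

    Section ``k`` is the (z, x) B-plane at the k-th section line (lines every
    ``section_spacing_um`` along y, the first at half-spacing from the
    specimen edge), laterally compressed by its shrink factor and smoothly
    warped.  The fresh-tissue width is recorded before shrinking, as it would
    be measured on the intact specimen.
    """
    nz, ny, nx = wide_field.shape
    sp_y, sp_x = wide_field.spacing_y_um, wide_field.spacing_x_um
    extent_y = ny * sp_y
    if section_spacing_um > extent_y:
        raise ValidationError(
            f"section spacing {section_spacing_um} um exceeds specimen extent {extent_y} um"
        )
    rng = np.random.default_rng(seed)
    positions = np.arange(section_spacing_um / 2, extent_y, section_spacing_um)
    if shrink_factors is None:
        shrink_factors = [1.18] * len(positions)
    if np.isscalar(shrink_factors):
        shrink_factors = [float(shrink_factors)] * len(positions)
    if len(shrink_factors) != len(positions):
        raise ValidationError(
            f"{len(positions)} section lines but {len(shrink_factors)} shrink factors"
        )

    data = np.where(np.isfinite(wide_field.intensity), wide_field.intensity, 0.0)
    sections = []
    for k, (pos, c) in enumerate(zip(positions, shrink_factors)):
        if c <= 0:
            raise ValidationError("shrink factor must be positive")
        y_idx = min(int(pos / sp_y), ny - 1)
        bplane = data[:, y_idx, :].astype(np.float64)
        row_mask = truth.specimen_mask[y_idx]
        fresh_width_um = float(row_mask.sum() * sp_x)

        img = bplane
        if c != 1.0:
            img = ndimage.zoom(img, (1.0, 1.0 / c), order=1)
        if warp_amplitude_um > 0:
            wz = ndimage.gaussian_filter(rng.standard_normal(img.shape), sigma=8, mode="reflect")
            wx = ndimage.gaussian_filter(rng.standard_normal(img.shape), sigma=8, mode="reflect")
            for w in (wz, wx):
                s = w.std()
                if s > 0:
                    w /= s
            zz, xx = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
            amp_z = warp_amplitude_um / wide_field.spacing_z_um
            amp_x = warp_amplitude_um / sp_x
            img = ndimage.map_coordinates(
                img, [zz + amp_z * wz, xx + amp_x * wx], order=1, mode="nearest"
            )
        sections.append(
            HistologySection(
                image=img.astype(np.float32),
                section_index=k,
                fresh_width_um=fresh_width_um,
                section_width_um=fresh_width_um / c,
                spacing_z_um=wide_field.spacing_z_um,
                spacing_x_um=sp_x,
                line_y_um=float(pos),
            )
        )
    return sections
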