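"""Data model and I/O for OCT volumes, scan-session logs and layer characterizations.

An :class:`OCTVolume` is the universal carrier for every 3-D image in the
toolkit: a single handheld (in vivo) tile, a benchtop (ex vivo) tile, or the
stitched wide-field volume of the excised cavity shaving.  Volumes are stored
on disk as multi-page TIFF stacks (one page per depth index ``z``) with a JSON
metadata sidecar of identical stem carrying the physical voxel spacings and
acquisition role.

Conventions
-----------
* Axes are ``[z, y, x]`` with 0-based indices; ``z`` increases with depth into
  the tissue.  A B-scan is a ``(z, x)`` slice at fixed ``y``; an en face plane
  is a ``(y, x)`` slice.
* All physical quantities in metadata are micrometres.
* Intensities are stored linear and non-negative; ``NaN`` marks no-data voxels
  (e.g. uncovered regions of a stitched mosaic).  Decibel conversion is a
  display/registration preprocessing step only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from ._exceptions import FormatError, MetadataError, ValidationError

__all__ = [
    "OCTVolume",
    "ScanSession",
    "TileRecord",
    "StressStrainCurve",
    "read_volume",
    "write_volume",
    "read_session_log",
    "read_stress_strain",
    "write_stress_strain",
    "to_decibels",
    "from_decibels",
    "VALID_ROLES",
    "VALID_FLAGS",
    "DB_FLOOR_FRACTION",
]

VALID_ROLES = frozenset({"in_vivo_tile", "ex_vivo_tile", "wide_field"})
VALID_FLAGS = frozenset({"poor_contact", "blood"})

#: Relative floor for the log conversion: intensities below this fraction of
#: the volume maximum are clamped before taking the logarithm.
DB_FLOOR_FRACTION = 1e-6


@dataclass
class OCTVolume:
    """A 3-D OCT backscatter volume with physical spacings and acquisition metadata.

    Parameters
    ----------
    intensity
        ``(nz, ny, nx)`` array of linear, non-negative backscatter values.
        ``NaN`` entries denote no-data voxels.
    spacing_z_um, spacing_y_um, spacing_x_um
        Physical voxel spacings in micrometres (all > 0).
    role
        One of ``in_vivo_tile`` (handheld probe, 6 x 6 x 3.5 mm^3 nominal),
        ``ex_vivo_tile`` (benchtop scanner) or ``wide_field`` (stitched mosaic).
    tile_id
        Optional identifier, e.g. the session grid cell.
    origin_um
        Physical ``(x, y)`` of voxel ``(., 0, 0)`` in the parent frame;
        ``(0, 0)`` for standalone volumes.
    """

    intensity: np.ndarray
    spacing_z_um: float
    spacing_y_um: float
    spacing_x_um: float
    role: str = "wide_field"
    tile_id: str | None = None
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.intensity)
        if arr.ndim != 3:
            raise ValidationError(f"intensity must be 3-D [z, y, x], got ndim={arr.ndim}")
        if any(s == 0 for s in arr.shape):
            raise ValidationError(f"empty volume: shape {arr.shape}")
        for name in ("spacing_z_um", "spacing_y_um", "spacing_x_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.role not in VALID_ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {sorted(VALID_ROLES)}")
        if arr.dtype.kind == "f":
            finite = arr[np.isfinite(arr)]
            if finite.size and finite.min() < 0:
                raise ValidationError("intensities must be non-negative")
        elif arr.dtype.kind == "i" and arr.size and arr.min() < 0:
            raise ValidationError("intensities must be non-negative")
        self.intensity = arr
        self.origin_um = (float(self.origin_um[0]), float(self.origin_um[1]))

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.intensity.shape)  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.intensity.shape[0]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in micrometres."""
        nz, ny, nx = self.intensity.shape
        return (nz * self.spacing_z_um, ny * self.spacing_y_um, nx * self.spacing_x_um)

    def with_intensity(self, intensity: np.ndarray, **kwargs) -> "OCTVolume":
        """Copy of this volume with new voxel data (metadata preserved unless overridden)."""
        return replace(self, intensity=intensity, **kwargs)

    def metadata(self) -> dict:
        return {
            "spacing_z_um": float(self.spacing_z_um),
            "spacing_y_um": float(self.spacing_y_um),
            "spacing_x_um": float(self.spacing_x_um),
            "role": self.role,
            "tile_id": self.tile_id,
            "origin_um": [float(self.origin_um[0]), float(self.origin_um[1])],
        }


@dataclass(frozen=True)
class TileRecord:
    """One entry of the in vivo scan-session log."""

    grid_row: int
    grid_col: int
    volume: str
    note_flags: frozenset = frozenset()

    @property
    def tile_id(self) -> str:
        return f"r{self.grid_row}c{self.grid_col}"


@dataclass
class ScanSession:
    """Ordered record of the 3x3 handheld acquisition around the cavity suture.

    The surgeon scans a grid of partially overlapping 6 x 6 mm^2 tiles centred
    on a suture tied at the suspicious region, stepping ~5 mm between scans.
    The session log is the coarse-placement prior for mosaicking; partial grids
    (unusable tiles dropped) are valid.
    """

    tiles: list[TileRecord]
    nominal_step_um: float = 5000.0
    anchor_index: int = 0

    def __post_init__(self):
        if not self.tiles:
            raise ValidationError("session has no tiles")
        cells = [(t.grid_row, t.grid_col) for t in self.tiles]
        if len(set(cells)) != len(cells):
            dup = sorted({c for c in cells if cells.count(c) > 1})
            raise ValidationError(f"duplicate grid cell(s) in session log: {dup}")
        for t in self.tiles:
            if t.grid_row not in (0, 1, 2) or t.grid_col not in (0, 1, 2):
                raise ValidationError(f"grid cell ({t.grid_row}, {t.grid_col}) outside the 3x3 grid")
            bad = set(t.note_flags) - VALID_FLAGS
            if bad:
                raise ValidationError(f"unknown note flag(s) {sorted(bad)}; allowed: {sorted(VALID_FLAGS)}")
        if not (0 <= self.anchor_index < len(self.tiles)):
            raise ValidationError(f"anchor_index {self.anchor_index} out of range for {len(self.tiles)} tiles")
        if self.nominal_step_um <= 0:
            raise ValidationError("nominal_step_um must be positive")

    @property
    def anchor(self) -> TileRecord:
        return self.tiles[self.anchor_index]


@dataclass
class StressStrainCurve:
    """Monotonic stress-strain characterization of the compliant surface layer.

    The layer is pre-characterized so that a measured layer strain can be
    mapped to the local axial stress at the tissue surface (the uniaxial
    stress assumption of compression elastography).
    """

    strain_points: np.ndarray
    stress_points_kPa: np.ndarray

    def __post_init__(self):
        eps = np.asarray(self.strain_points, dtype=float)
        sig = np.asarray(self.stress_points_kPa, dtype=float)
        if eps.ndim != 1 or sig.shape != eps.shape or eps.size < 2:
            raise ValidationError("curve needs matching 1-D strain/stress arrays with >= 2 points")
        if not (np.all(np.diff(eps) > 0) and np.all(np.diff(sig) > 0)):
            raise ValidationError("stress-strain curve must be strictly increasing in both coordinates")
        if eps[0] != 0.0 or sig[0] != 0.0:
            raise ValidationError("stress-strain curve must start at (0, 0)")
        self.strain_points = eps
        self.stress_points_kPa = sig

    @property
    def max_strain(self) -> float:
        return float(self.strain_points[-1])

    def stress_at(self, strain, extrapolate: bool = False):
        """Piecewise-linear stress (kPa) at the given strain(s)."""
        strain = np.asarray(strain, dtype=float)
        if not extrapolate and np.any((strain < 0) | (strain > self.max_strain)):
            raise ValidationError(
                f"strain outside characterized range [0, {self.max_strain}] and extrapolation disabled"
            )
        if extrapolate:
            slope = (self.stress_points_kPa[-1] - self.stress_points_kPa[-2]) / (
                self.strain_points[-1] - self.strain_points[-2]
            )
            out = np.interp(strain, self.strain_points, self.stress_points_kPa)
            over = strain > self.max_strain
            out = np.where(over, self.stress_points_kPa[-1] + slope * (strain - self.max_strain), out)
            return out
        return np.interp(strain, self.strain_points, self.stress_points_kPa)

    def strain_at(self, stress_kPa):
        """Inverse map: strain at the given stress(es), within the characterized range."""
        stress_kPa = np.asarray(stress_kPa, dtype=float)
        return np.interp(stress_kPa, self.stress_points_kPa, self.strain_points)


# ---------------------------------------------------------------------------
# Volume I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(vol: OCTVolume, path) -> None:
    """Write a volume as a z-ordered multi-page TIFF plus JSON sidecar.

    Integer volumes round-trip bit exactly; floats to machine precision.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    arr = vol.intensity
    if arr.dtype == np.float64:  # TIFF readers are happier with float32; keep 64-bit when asked
        arr = arr  # tifffile handles float64 fine; preserve exactly
    tifffile.imwrite(path, arr, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(vol.metadata(), indent=2))


def read_volume(path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing JSON sidecar for {path} (expected {sidecar})")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise MetadataError(f"unparseable sidecar {sidecar}: {e}") from e
    required = {"spacing_z_um", "spacing_y_um", "spacing_x_um", "role"}
    missing = required - meta.keys()
    if missing:
        raise MetadataError(f"sidecar {sidecar} missing fields: {sorted(missing)}")
    try:
        arr = tifffile.imread(path)
    except Exception as e:  # tifffile raises various things on malformed stacks
        raise FormatError(f"cannot read TIFF stack {path}: {e}") from e
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"TIFF stack {path} has inconsistent page shapes or ndim={arr.ndim}")
    return OCTVolume(
        intensity=arr,
        spacing_z_um=meta["spacing_z_um"],
        spacing_y_um=meta["spacing_y_um"],
        spacing_x_um=meta["spacing_x_um"],
        role=meta["role"],
        tile_id=meta.get("tile_id"),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0))),
    )


# ---------------------------------------------------------------------------
# Session log
# ---------------------------------------------------------------------------

def _parse_flags(raw) -> frozenset:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    if isinstance(raw, (list, tuple, set, frozenset)):
        return frozenset(str(f) for f in raw if str(f))
    s = str(raw).strip()
    if not s:
        return frozenset()
    return frozenset(p.strip() for p in s.split(";") if p.strip())


def read_session_log(path, nominal_step_um: float = 5000.0) -> ScanSession:
    """Read a scan-session log (CSV or JSON) into a validated :class:`ScanSession`.

    CSV columns: ``grid_row, grid_col, volume, flags, is_anchor`` with flags
    semicolon-separated.  JSON: list of objects with the same keys, plus an
    optional top-level ``nominal_step_um``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            rows = payload["tiles"]
            nominal_step_um = float(payload.get("nominal_step_um", nominal_step_um))
        else:
            rows = payload
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    required = {"grid_row", "grid_col", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"session log missing columns: {sorted(missing)}")
    tiles = []
    anchor_index = None
    for i, row in df.iterrows():
        tiles.append(
            TileRecord(
                grid_row=int(row["grid_row"]),
                grid_col=int(row["grid_col"]),
                volume=str(row["volume"]),
                note_flags=_parse_flags(row.get("flags")),
            )
        )
        if bool(row.get("is_anchor", False)):
            if anchor_index is not None:
                raise ValidationError("multiple tiles marked is_anchor")
            anchor_index = len(tiles) - 1
    if anchor_index is None:
        raise ValidationError("no tile marked is_anchor (the cavity-suture tile)")
    return ScanSession(tiles=tiles, nominal_step_um=nominal_step_um, anchor_index=anchor_index)


def read_stress_strain(path) -> StressStrainCurve:
    """Read a layer characterization CSV with columns ``strain, stress_kPa``."""
    df = pd.read_csv(path)
    missing = {"strain", "stress_kPa"} - set(df.columns)
    if missing:
        raise FormatError(f"stress-strain CSV missing columns: {sorted(missing)}")
    return StressStrainCurve(df["strain"].to_numpy(), df["stress_kPa"].to_numpy())


def write_stress_strain(curve: StressStrainCurve, path) -> None:
    pd.DataFrame({"strain": curve.strain_points, "stress_kPa": curve.stress_points_kPa}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Decibel conversion
# ---------------------------------------------------------------------------

def to_decibels(data, floor_fraction: float = DB_FLOOR_FRACTION) -> np.ndarray:
    """Convert linear intensity to dB: ``10 * log10(I / I_ref)`` with ``I_ref = 1``.

    Values below ``floor_fraction * max`` (including zeros) are clamped to the
    floor so the logarithm stays finite; NaN no-data entries propagate.
    """
    arr = np.asarray(data.intensity if isinstance(data, OCTVolume) else data, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0 or finite.max() <= 0:
        return np.full_like(arr, np.nan)
    floor = floor_fraction * finite.max()
    with np.errstate(invalid="ignore"):
        return 10.0 * np.log10(np.maximum(arr, floor))


def from_decibels(db) -> np.ndarray:
    """Inverse of :func:`to_decibels` above the clamping floor."""
    return 10.0 ** (np.asarray(db, dtype=float) / 10.0)
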