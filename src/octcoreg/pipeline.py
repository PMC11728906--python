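"""End-to-end pipeline: phantom -> stitch -> mosaic -> histology map -> QME -> report.

The pipeline mirrors the clinical workflow on synthetic data: a wide-field
shaving phantom stands in for the excised specimen, benchtop tiles are cut
and re-stitched, a 3x3 handheld session with pose jitter and degradation is
extracted and co-registered back via the suture fiducial, the section grid
and B-scan matches are computed, and a compression pair is pushed through
the elastography chain.  Every stage draws its randomness from sub-seeds
fanned out of one global seed, so a run is deterministic end to end; stage
parameters are logged into the report bundle for provenance.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from ._exceptions import StageError
from . import phantom as ph
from .fiducial import detect_suture
from .histology_map import match_bscan, overlay_grid
from .mosaic import SearchParams, register_session, summarize
from .qme import qme_chain
from .surface_enface import detect_surface, extract_enface
from .volume_io import OCTVolume, ScanSession, StressStrainCurve, TileRecord, to_decibels, write_volume
from .widefield_stitch import plan_tiles, stitch

__all__ = ["PipelineConfig", "run_pipeline"]


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    extent_um: tuple[float, float, float] = (12000.0, 12000.0, 1200.0)
    spacing_lateral_um: float = 40.0
    spacing_axial_um: float = 12.0
    adipose_fraction: float = 0.3
    suture_length_um: float = 2500.0
    suture_width_um: float = 250.0
    suture_axis_deg: float = 15.0
    surface_topography_amplitude_um: float = 60.0


class MosaicConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tile_extent_um: float = 4000.0
    step_um: float = 3300.0
    pose_jitter_um: float = 300.0
    pose_jitter_deg: float = 3.0
    noise_sigma: float = 0.03
    search_trans_um: float = 800.0
    search_theta_deg: float = 5.0
    search_theta_step_deg: float = 0.5
    search_dz_um: float = 24.0
    score_threshold: float = 0.3
    consistency_threshold_um: float = 1500.0


class HistologyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    section_spacing_um: float = 4500.0
    shrink_min: float = 1.1
    shrink_max: float = 1.25
    warp_amplitude_um: float = 30.0
    search_halfwidth_um: float = 600.0


class QMEConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    crop_extent_um: float = 3000.0
    layer_thickness_um: float = 500.0
    actuation_um: float = 25.0
    layer_strain_points: tuple[float, ...] = (0.0, 0.1, 0.2)
    layer_stress_points_kPa: tuple[float, ...] = (0.0, 2.0, 4.0)


class PipelineConfig(BaseModel):
    """Schema-validated configuration of a full run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "coreg_out"
    use_phantom: bool = True
    wide_field_path: str | None = None
    session_path: str | None = None
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    mosaic: MosaicConfig = Field(default_factory=MosaicConfig)
    histology: HistologyConfig = Field(default_factory=HistologyConfig)
    qme: QMEConfig = Field(default_factory=QMEConfig)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _composite_figure(wf_plane, placements, grid, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    db = to_decibels(wf_plane.image)
    ax.imshow(
        db,
        cmap="gray",
        extent=(0, wf_plane.image.shape[1] * wf_plane.spacing_x_um / 1000,
                wf_plane.image.shape[0] * wf_plane.spacing_y_um / 1000, 0),
    )
    for y in grid.line_positions_um:
        ax.axhline(y / 1000, color="orange", ls="--", lw=1)
    for p, extent in placements:
        half = extent / 2000.0
        t = math.radians(p.pose.theta_deg)
        c, s = math.cos(t), math.sin(t)
        corners = np.array([[-half, -half], [half, -half], [half, half], [-half, half], [-half, -half]])
        world = np.array(
            [
                (p.pose.tx_um / 1000 + c * x - s * y, p.pose.ty_um / 1000 + s * x + c * y)
                for x, y in corners
            ]
        )
        color = "lime" if p.success else "red"
        ax.plot(world[:, 0], world[:, 1], color=color, lw=1.5)
        ax.text(p.pose.tx_um / 1000, p.pose.ty_um / 1000, p.tile_id, color=color, fontsize=7, ha="center")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title("wide-field en face with co-registered tiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, 6)
    summary: dict = {"seed": config.seed, "stages": {}, "parameters": json.loads(config.model_dump_json())}

    # --- stage 1: phantom ------------------------------------------------
    try:
        pc = config.phantom
        ex, ey, ez = pc.extent_um
        spec = ph.PhantomSpec(
            extent_um=(ex, ey, ez),
            spacing_lateral_um=pc.spacing_lateral_um,
            spacing_axial_um=pc.spacing_axial_um,
            adipose_fraction=pc.adipose_fraction,
            suture=ph.SutureSpec(
                centroid_um=(ex / 2, ey / 2),
                length_um=pc.suture_length_um,
                width_um=pc.suture_width_um,
                axis_deg=pc.suture_axis_deg,
            ),
            surface_topography_amplitude_um=pc.surface_topography_amplitude_um,
            seed=seeds[0],
        )
        if not config.use_phantom:
            raise StageError("phantom", "external inputs not configured; enable use_phantom or set wide_field_path")
        wide_field, truth = ph.generate_shaving_phantom(spec)
        summary["stages"]["phantom"] = {"shape": list(wide_field.shape), "adipose_fraction_realized": float(truth.tissue_class.mean())}
    except StageError:
        raise
    except Exception as e:
        raise StageError("phantom", str(e)) from e

    # --- stage 2: ex vivo tiling + stitch --------------------------------
    try:
        plan = plan_tiles((ex, ey), tile_fov_um=ex * 0.6, step_um=ex * 0.45)
        sp = wide_field.spacing_x_um
        tiles = []
        for x0, y0 in plan.positions_um:
            i0, j0 = int(round(x0 / sp)), int(round(y0 / sp))
            ni = min(int(round(plan.tile_fov_um[0] / sp)), wide_field.shape[2] - i0)
            nj = min(int(round(plan.tile_fov_um[1] / sp)), wide_field.shape[1] - j0)
            tiles.append(
                OCTVolume(
                    wide_field.intensity[:, j0 : j0 + nj, i0 : i0 + ni],
                    spacing_z_um=wide_field.spacing_z_um,
                    spacing_y_um=wide_field.spacing_y_um,
                    spacing_x_um=wide_field.spacing_x_um,
                    role="ex_vivo_tile",
                    origin_um=(i0 * sp, j0 * sp),
                )
            )
        stitched = stitch(tiles)
        cov = np.isfinite(stitched.intensity[0]).mean()
        summary["stages"]["stitch"] = {"n_tiles": len(tiles), "coverage": float(cov)}
        write_volume(stitched, out / "widefield.tif")
    except Exception as e:
        raise StageError("stitch", str(e)) from e

    # --- stage 3: in vivo session + mosaic -------------------------------
    try:
        mc = config.mosaic
        rng = np.random.default_rng(seeds[1])
        centre = np.array([ex / 2, ey / 2])
        records, volumes, true_poses = [], {}, {}
        for row in range(3):
            for col in range(3):
                nominal = centre + np.array([(col - 1) * mc.step_um, (row - 1) * mc.step_um])
                jitter = rng.uniform(-mc.pose_jitter_um, mc.pose_jitter_um, 2)
                theta = float(rng.uniform(-mc.pose_jitter_deg, mc.pose_jitter_deg))
                pose = ph.RigidPose2D(*(nominal + jitter), theta_deg=theta)
                rec = TileRecord(grid_row=row, grid_col=col, volume=f"r{row}c{col}")
                records.append(rec)
                volumes[rec.tile_id] = ph.extract_tile(
                    wide_field,
                    truth,
                    pose,
                    degrade=ph.Degrade(noise_sigma=mc.noise_sigma),
                    tile_extent_um=mc.tile_extent_um,
                    tile_id=rec.tile_id,
                    seed=int(rng.integers(2**31 - 1)),
                )
                true_poses[rec.tile_id] = pose
        session = ScanSession(tiles=records, nominal_step_um=mc.step_um, anchor_index=4)

        wf_surface = detect_surface(stitched)
        wf_plane = extract_enface(stitched, wf_surface, 100.0)
        anchor_vol = volumes[session.anchor.tile_id]
        anchor_plane = extract_enface(anchor_vol, detect_surface(anchor_vol), 100.0)
        mark_iv = detect_suture(anchor_plane)
        mark_ev = detect_suture(wf_plane)
        if mark_iv is None or mark_ev is None:
            raise StageError("mosaic", "suture fiducial not detected in anchor or wide-field plane")
        search = SearchParams(
            trans_um=mc.search_trans_um,
            theta_deg=mc.search_theta_deg,
            theta_step_deg=mc.search_theta_step_deg,
            dz_um=mc.search_dz_um,
        )
        placements = register_session(
            session,
            volumes,
            stitched,
            mark_iv,
            mark_ev,
            search=search,
            score_threshold=mc.score_threshold,
            consistency_threshold_um=mc.consistency_threshold_um,
        )
        table = summarize(placements)
        table.to_csv(out / "summary_table.csv", index=False)
        pose_errors = {
            p.tile_id: float(
                math.hypot(p.pose.tx_um - true_poses[p.tile_id].tx_um, p.pose.ty_um - true_poses[p.tile_id].ty_um)
            )
            for p in placements
        }
        placements_json = [
            {
                "tile_id": p.tile_id,
                "pose": {"tx_um": p.pose.tx_um, "ty_um": p.pose.ty_um, "theta_deg": p.pose.theta_deg, "dz_um": p.pose.dz_um},
                "score": p.score,
                "success": p.success,
                "tissue_class": p.tissue_class,
                "overlap_consistency_um": p.overlap_consistency_um,
                "note_flags": list(p.note_flags),
                "pose_error_um_vs_truth": pose_errors[p.tile_id],
            }
            for p in placements
        ]
        (out / "placements.json").write_text(json.dumps(placements_json, indent=2, sort_keys=True))
        summary["stages"]["mosaic"] = {
            "n_tiles": len(placements),
            "n_success": int(sum(p.success for p in placements)),
            "mean_pose_error_um": float(np.mean(list(pose_errors.values()))),
            "fiducial_multiplicity": mark_ev.multiplicity,
        }
    except StageError:
        raise
    except Exception as e:
        raise StageError("mosaic", str(e)) from e

    # --- stage 4: histology map ------------------------------------------
    try:
        hc = config.histology
        rng_h = np.random.default_rng(seeds[2])
        grid = overlay_grid(wf_plane, hc.section_spacing_um)
        n_sec = len(np.arange(hc.section_spacing_um / 2, ey, hc.section_spacing_um))
        shrinks = [float(rng_h.uniform(hc.shrink_min, hc.shrink_max)) for _ in range(max(n_sec, 1))]
        sections = ph.generate_histology_sections(
            wide_field, truth, hc.section_spacing_um, shrink_factors=shrinks[: max(n_sec, 1)],
            warp_amplitude_um=hc.warp_amplitude_um, seed=seeds[3],
        )
        rows = []
        for sec in sections:
            idx, score = match_bscan(sec, stitched, sec.line_y_um, search_halfwidth_um=hc.search_halfwidth_um)
            true_idx = min(int(sec.line_y_um / wide_field.spacing_y_um), wide_field.shape[1] - 1)
            rows.append(
                {
                    "section_index": sec.section_index,
                    "line_y_um": sec.line_y_um,
                    "fresh_width_um": sec.fresh_width_um,
                    "section_width_um": sec.section_width_um,
                    "correction_factor": sec.correction_factor,
                    "matched_bscan": idx,
                    "true_bscan": true_idx,
                    "dice": score,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "sections.csv", index=False)
        summary["stages"]["histology"] = {
            "n_sections": len(rows),
            "max_index_error": int(max(abs(r["matched_bscan"] - r["true_bscan"]) for r in rows)),
        }
    except Exception as e:
        raise StageError("histology", str(e)) from e

    # --- stage 5: QME -----------------------------------------------------
    if config.qme.enabled:
        try:
            qc = config.qme
            curve = StressStrainCurve(np.array(qc.layer_strain_points), np.array(qc.layer_stress_points_kPa))
            n_crop = int(qc.crop_extent_um / wide_field.spacing_x_um)
            j0 = wide_field.shape[1] // 2 - n_crop // 2
            i0 = wide_field.shape[2] // 2 - n_crop // 2
            crop = OCTVolume(
                wide_field.intensity[:, j0 : j0 + n_crop, i0 : i0 + n_crop],
                spacing_z_um=wide_field.spacing_z_um,
                spacing_y_um=wide_field.spacing_y_um,
                spacing_x_um=wide_field.spacing_x_um,
                role="wide_field",
            )
            crop_truth = ph.GroundTruth(
                tissue_class=truth.tissue_class[j0 : j0 + n_crop, i0 : i0 + n_crop],
                feature_masks={},
                suture_mask=None,
                suture_centroid_um=None,
                suture_axis_deg=None,
                elasticity_map_kPa=truth.elasticity_map_kPa[j0 : j0 + n_crop, i0 : i0 + n_crop],
                surface_depth_um=truth.surface_depth_um[j0 : j0 + n_crop, i0 : i0 + n_crop],
                specimen_mask=truth.specimen_mask[j0 : j0 + n_crop, i0 : i0 + n_crop],
            )
            pre, post, ctruth = ph.simulate_compression_pair(
                crop, crop_truth, curve, layer_thickness_um=qc.layer_thickness_um,
                actuation_um=qc.actuation_um, seed=seeds[4],
            )
            E, extras = qme_chain(pre, post, curve, layer_thickness_um=qc.layer_thickness_um)
            emap = OCTVolume(
                np.where(E.valid, E.E_kPa, 0.0).astype(np.float32),
                spacing_z_um=E.spacing_z_um,
                spacing_y_um=E.spacing_y_um,
                spacing_x_um=E.spacing_x_um,
                role="wide_field",
                tile_id="elasticity_kPa",
            )
            write_volume(emap, out / "elasticity.tif")
            sel = E.valid.copy()
            sel[: ctruth.n_layer + 8] = False
            dense = ~crop_truth.tissue_class.astype(bool)
            sel &= dense[None]
            med = float(np.nanmedian(E.E_kPa[sel])) if sel.any() else float("nan")
            true_med = float(np.median(crop_truth.elasticity_map_kPa[dense])) if dense.any() else float("nan")
            summary["stages"]["qme"] = {
                "median_E_kPa": med,
                "true_dense_E_kPa": true_med,
                "stress_kPa_median": float(np.median(extras["stress_kPa"])),
                "valid_fraction": float(E.valid.mean()),
            }
        except Exception as e:
            raise StageError("qme", str(e)) from e

    # --- report -----------------------------------------------------------
    try:
        _composite_figure(wf_plane, [(p, config.mosaic.tile_extent_um) for p in placements], grid, out / "composite.png")
    except Exception as e:
        raise StageError("report", str(e)) from e
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
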