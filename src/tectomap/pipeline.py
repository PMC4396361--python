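"""Pipeline orchestration: composes the imaging-map, retinotopy, concentric
prediction and comparison stages, and the electrophysiology columnar
analyses, into deterministic artifact sets with a manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import io as tio
from .compare import (
    MapComparison,
    PenetrationSummary,
    columnar_summary,
    compare_orientation_to_concentric,
    penetration_concentric_test,
)
from .config import PipelineConfig
from .geometry import (
    MonitorGeometry,
    PatchFit,
    RetinotopyMaps,
    build_concentric_map,
    fit_patch_gaussian,
    interpolate_retinotopy,
)
from .imaging import (
    ImagingStack,
    StimulusEvent,
    anova_significance_map,
    condition_mean_maps,
    condition_trial_maps,
    orientation_polar_map,
    retinotopy_argmax_map,
    single_condition_map,
)
from .maps import AxialMap, ScalarMap
from .render import axial_to_rgb, patch_to_rgb

logger = logging.getLogger(__name__)

__all__ = ["ImagingResult", "analyze_imaging", "run_imaging_pipeline", "run_ephys_pipeline"]


@dataclass
class ImagingResult:
    patch_map: ScalarMap
    patch_amplitude: ScalarMap
    patch_fits: list[PatchFit]
    retinotopy: RetinotopyMaps
    orientation_map: AxialMap
    per_condition: np.ndarray
    anova_p: ScalarMap
    single_condition: dict[float, ScalarMap]
    concentric_map: AxialMap
    comparison: MapComparison


def _validate_inputs(
    stack: ImagingStack, events: list[StimulusEvent], geom: MonitorGeometry
) -> None:
    """Fail fast on mutually inconsistent inputs, naming the first violation."""
    t_end = stack.t0_s + stack.duration_s
    for ev in events:
        if ev.onset_s < stack.t0_s or ev.offset_s > t_end:
            raise ValueError(
                f"inconsistent inputs: event at {ev.onset_s:.2f}s lies outside the "
                f"recording [{stack.t0_s:.2f}, {t_end:.2f}]s"
            )
        if ev.kind == "patch" and not (0 <= ev.patch_id < geom.n_patches):
            raise ValueError(
                f"inconsistent inputs: patch id {ev.patch_id} missing from the "
                f"{geom.n_patches}-patch geometry"
            )


def analyze_imaging(
    stack: ImagingStack,
    events: list[StimulusEvent],
    geom: MonitorGeometry,
    cfg: PipelineConfig | None = None,
) -> ImagingResult:
    """Run the full imaging analysis in memory.

    Stages: per-trial ΔF/F (reference-corrected, 33 µm smoothed) -> best-patch
    retinotopy and per-patch Gaussian fits -> interpolated azimuth/elevation
    inside the patch hull -> pixelwise orientation polar map, ANOVA
    significance map and single-condition maps -> concentric prediction
    (132 µm smoothed) -> measured-vs-predicted comparison.
    """
    cfg = cfg or PipelineConfig()
    _validate_inputs(stack, events, geom)
    ref_roi = cfg.ref_roi_slices()

    patch_trials = condition_trial_maps(stack, events, "patch", ref_roi)
    grating_trials = condition_trial_maps(stack, events, "grating", ref_roi)
    if not patch_trials or not grating_trials:
        raise ValueError("inconsistent inputs: need both patch and grating events")
    patch_means = condition_mean_maps(patch_trials, cfg.sigma_map_um, stack.pixel_size_um)
    grating_means = condition_mean_maps(grating_trials, cfg.sigma_map_um, stack.pixel_size_um)

    patch_map, patch_amp = retinotopy_argmax_map(patch_means)
    fits = []
    for pid in sorted(patch_means):
        fits.append(
            fit_patch_gaussian(
                patch_means[pid],
                patch_id=int(pid),
                subtract_dff=cfg.patch_subtract_dff,
                include_threshold_dff=cfg.patch_include_dff,
                subtract_mode=cfg.patch_subtract_mode,
            )
        )
    retino = interpolate_retinotopy(fits, geom, stack.shape)

    orientation_map, per_condition = orientation_polar_map(grating_means)
    anova_p = anova_significance_map(grating_trials, alpha=cfg.alpha)

    dirs = sorted(grating_means)
    single = {}
    for d in dirs:
        if d < 180 and (d + 180) in grating_means:
            single[d] = single_condition_map(grating_means, [d, d + 180])

    concentric = build_concentric_map(
        retino,
        sigma_um=cfg.sigma_concentric_um,
        pixel_size_um=stack.pixel_size_um,
        ipsi_azimuth_sign=geom.ipsi_azimuth_sign,
    )
    comparison = compare_orientation_to_concentric(
        orientation_map,
        concentric,
        min_mean_response=cfg.min_mean_response,
        per_condition=per_condition,
        filter_mode=cfg.response_filter_mode,
        n_permutations=cfg.n_map_permutations,
        seed=cfg.seed,
    )
    return ImagingResult(
        patch_map=patch_map,
        patch_amplitude=patch_amp,
        patch_fits=fits,
        retinotopy=retino,
        orientation_map=orientation_map,
        per_condition=per_condition,
        anova_p=anova_p,
        single_condition=single,
        concentric_map=concentric,
        comparison=comparison,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, files: list[Path], params: dict) -> dict:
    manifest = {
        "parameters": params,
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_imaging_pipeline(cfg: PipelineConfig) -> dict:
    """Disk-to-disk imaging pipeline; returns the manifest."""
    if not cfg.stack_path or not cfg.schedule_path:
        raise ValueError("config must set stack_path and schedule_path")
    stack = tio.read_stack(cfg.stack_path)
    events = tio.read_schedule(cfg.schedule_path)
    geom = cfg.monitor_geometry()
    res = analyze_imaging(stack, events, geom, cfg)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_scalar(m: ScalarMap, name: str) -> None:
        p = outdir / name
        tio.save_scalar_map(m, p)
        files.append(p)

    save_scalar(res.patch_map, "retinotopy_patch.tif")
    save_scalar(res.patch_amplitude, "retinotopy_amplitude.tif")
    save_scalar(res.retinotopy.azimuth_deg, "azimuth.tif")
    save_scalar(res.retinotopy.elevation_deg, "elevation.tif")
    save_scalar(res.anova_p, "anova_p.tif")
    for d, m in res.single_condition.items():
        save_scalar(m, f"single_condition_{int(d):03d}.tif")
    for m, name in ((res.orientation_map, "orientation.tif"), (res.concentric_map, "concentric.tif")):
        p = outdir / name
        tio.save_axial_map(m, p)
        files.append(p)
    for m, name in (
        (res.orientation_map, "orientation_hsv.tif"),
        (res.concentric_map, "concentric_hsv.tif"),
    ):
        p = outdir / name
        tifffile.imwrite(p, axial_to_rgb(m), photometric="rgb")
        files.append(p)
    p = outdir / "retinotopy_hsv.tif"
    tifffile.imwrite(
        p,
        patch_to_rgb(res.patch_map, res.patch_amplitude, cfg.monitor_geometry().n_patches),
        photometric="rgb",
    )
    files.append(p)

    fits_df = pd.DataFrame(
        [
            {
                "patch_id": f.patch_id,
                "centre_row_px": f.centre_px[0],
                "centre_col_px": f.centre_px[1],
                "sigma_row_px": f.sigmas_px[0],
                "sigma_col_px": f.sigmas_px[1],
                "amplitude_dff": f.amplitude_dff,
                "included": f.included,
            }
            for f in res.patch_fits
        ]
    )
    p = outdir / "patch_fits.csv"
    fits_df.to_csv(p, index=False)
    files.append(p)

    p = outdir / "comparison.json"
    p.write_text(json.dumps(res.comparison.to_dict(), indent=2))
    files.append(p)
    hist_df = pd.DataFrame(
        {
            "bin_left_deg": res.comparison.bin_edges[:-1],
            "bin_right_deg": res.comparison.bin_edges[1:],
            "count": res.comparison.diff_histogram,
        }
    )
    p = outdir / "diff_histogram.csv"
    hist_df.to_csv(p, index=False)
    files.append(p)

    return _write_manifest(outdir, files, asdict(cfg))


def run_ephys_pipeline(cfg: PipelineConfig) -> dict:
    """Disk-to-disk electrophysiology pipeline; returns the manifest."""
    if not cfg.ephys_table_path:
        raise ValueError("config must set ephys_table_path")
    table = pd.read_csv(cfg.ephys_table_path)
    if len(table) == 0:
        raise ValueError("inconsistent inputs: empty unit table")
    pen_table, shuffle, rayleigh = columnar_summary(
        table,
        n_shuffles=cfg.n_shuffles,
        seed=cfg.seed,
        min_evoked_hz=cfg.min_evoked_hz,
        pref_method=cfg.pref_method,
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    p = outdir / "penetrations.csv"
    pen_table.to_csv(p, index=False)
    files.append(p)

    report = {"shuffle_test": shuffle.to_dict()}
    if rayleigh is not None:
        report["rayleigh_on_circular_means"] = {
            "p_value": rayleigh.p_value,
            "z": rayleigh.z,
            "n": rayleigh.n,
        }
    if pen_table["rf_azimuth_deg"].notna().all():
        geom = cfg.monitor_geometry()
        summaries = [
            PenetrationSummary(
                penetration_id=row.penetration_id,
                circ_mean_deg=row.circ_mean_deg,
                circ_var=row.circ_var,
                n_units=int(row.n_units),
                rf_azimuth_deg=row.rf_azimuth_deg,
                rf_elevation_deg=row.rf_elevation_deg,
            )
            for row in pen_table.itertuples()
            if np.isfinite(row.circ_mean_deg)
        ]
        conc_table, conc_corr = penetration_concentric_test(
            summaries, ipsi_azimuth_sign=geom.ipsi_azimuth_sign
        )
        p = outdir / "concentric_penetrations.csv"
        conc_table.to_csv(p, index=False)
        files.append(p)
        report["concentric_test"] = {
            "circ_corr": conc_corr,
            "n_penetrations": int(len(conc_table)),
            "degenerate_predictor": bool(conc_table.attrs.get("degenerate_predictor", False)),
        }
    p = outdir / "ephys_report.json"
    p.write_text(json.dumps(report, indent=2))
    files.append(p)
    return _write_manifest(outdir, files, asdict(cfg))
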