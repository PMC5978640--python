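"""One-call QA pipeline: volume in, consolidated report out.

Runs positioning first, then every enabled analysis with pose-corrected
ROI coordinates, and collects one :class:`~tomoqa.io.ReportRecord` per
metric.  A failure in one analysis is recorded against that metric
without aborting the rest; the pipeline result says whether any hard
error occurred so a caller (or the CLI) can exit non-zero.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import PhantomGeometry, default_geometry
from .io import ReportRecord, dump_json, read_volume, write_report
from .positioning import PoseEstimate, estimate_pose, identity_pose, \
    locate_markers
from .volume import ReconVolume

#: metric families produced by a default single-volume run
METRIC_FAMILIES = (
    "positioning",
    "chest_wall",
    "slice_width",
    "slice_incrementation",
    "z_bead_spacing",
    "asf",
    "mtf",
    "uniformity",
    "snr_cnr",
    "low_contrast",
)


@dataclass
class PipelineConfig:
    input_path: str
    input_format: str | None = None  # sniffed when None
    geometry_path: str | None = None  # bundled default when None
    output_dir: str = "."
    enabled: dict = field(default_factory=dict)  # family -> bool (default on)
    step_visibility_k: float = 2.0
    detection_cnr: float = 1.0
    deconvolve_bead: bool = False
    deconvolution_eps: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_visibility_k <= 0 or self.detection_cnr <= 0 \
                or self.deconvolution_eps <= 0:
            raise ValueError("thresholds must be positive")
        unknown = set(self.enabled) - set(METRIC_FAMILIES)
        if unknown:
            raise ValueError(f"unknown metric families: {sorted(unknown)}")

    def is_enabled(self, family: str) -> bool:
        return bool(self.enabled.get(family, True))

    def to_dict(self) -> dict:
        return {"input_path": str(self.input_path),
                "input_format": self.input_format,
                "geometry_path": self.geometry_path,
                "enabled": dict(self.enabled),
                "step_visibility_k": self.step_visibility_k,
                "detection_cnr": self.detection_cnr,
                "deconvolve_bead": self.deconvolve_bead,
                "deconvolution_eps": self.deconvolution_eps,
                "seed": self.seed}

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: list
    errors: dict  # family -> message
    pose: PoseEstimate | None
    report_paths: tuple | None = None

    @property
    def hard_error(self) -> bool:
        return bool(self.errors)


def _load_geometry(config: PipelineConfig) -> PhantomGeometry:
    if config.geometry_path:
        return PhantomGeometry.from_json(config.geometry_path)
    return default_geometry()


def analyze_volume(vol: ReconVolume, geometry: PhantomGeometry,
                   config: PipelineConfig) -> PipelineResult:
    """Run all enabled analyses on an in-memory volume."""
    records: list[ReportRecord] = []
    errors: dict[str, str] = {}
    pose = identity_pose(geometry)

    def run(family, fn):
        if not config.is_enabled(family):
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - fault isolation per metric
            errors[family] = str(exc)
            records.append(ReportRecord(
                name=family, value=float("nan"), units="1",
                provenance={"error": str(exc)}, status="failed"))

    def _positioning():
        nonlocal pose
        cents = locate_markers(vol, geometry)
        pose = estimate_pose(cents, geometry)
        records.append(ReportRecord(
            name="pose", units="degree",
            value={"roll": pose.roll, "pitch": pose.pitch, "yaw": pose.yaw,
                   "translation_x_mm": pose.translation[0],
                   "translation_y_mm": pose.translation[1]},
            provenance={"marker_centroids_xyz_mm": cents.tolist(),
                        "residual_mm": pose.residual_mm,
                        "convention": "intrinsic z-y-x (yaw, pitch, roll)"},
            status="ok" if all(pose.reliable.values()) else "flagged"))

    run("positioning", _positioning)

    def _chest_wall():
        from .chest_wall import measure_gauge
        readings = [measure_gauge(vol, g, pose, k=config.step_visibility_k)
                    for g in geometry.gauges]
        for r in readings:
            records.append(ReportRecord(
                name=f"chest_wall/{r.gauge_id}", value=r.missing_tissue,
                units="mm",
                provenance={"visible_steps": r.visible_steps,
                            "visible_extent_mm": r.visible_extent,
                            "interpolated_mm": r.missing_tissue_interpolated,
                            "slice_index": r.slice_index,
                            "visibility_k": config.step_visibility_k},
                status="flagged" if r.flagged else "ok"))
        records.append(ReportRecord(
            name="chest_wall/mean_missing_tissue",
            value=float(np.mean([r.missing_tissue for r in readings])),
            units="mm", provenance={"n_gauges": len(readings)}))

    run("chest_wall", _chest_wall)

    def _slice_width():
        from .slice_geometry import slice_width
        widths = {r.ramp_id: slice_width(vol, r, pose)
                  for r in geometry.ramps}
        for rid, w in widths.items():
            records.append(ReportRecord(
                name=f"slice_width/{rid}", value=w, units="mm",
                provenance={"method": "SSP FWHM, mean over central slices"}))
        records.append(ReportRecord(
            name="slice_width/mean", value=float(np.mean(list(widths.values()))),
            units="mm", provenance={"ramps": sorted(widths)}))

    run("slice_width", _slice_width)

    def _slice_increment():
        from .slice_geometry import slice_incrementation
        res = slice_incrementation(vol, geometry.ramps[0], pose)
        records.append(ReportRecord(
            name="slice_incrementation", value=res.mean_mm, units="mm",
            provenance={"differences_mm": res.differences.tolist(),
                        "slice_indices": res.slice_indices},
            status="flagged" if res.outliers.any() else "ok"))

    run("slice_incrementation", _slice_increment)

    def _z_spacing():
        from .slice_geometry import z_bead_spacing
        spac = z_bead_spacing(vol, geometry, pose)
        records.append(ReportRecord(
            name="z_bead_spacing", value=spac.tolist(), units="mm",
            provenance={"n_beads": len(geometry.z_beads),
                        "mean_mm": float(np.mean(spac))}))

    run("z_bead_spacing", _z_spacing)

    def _asf():
        from .slice_geometry import asf
        bead = geometry.z_beads[len(geometry.z_beads) // 2]
        ax, ay = asf(vol, bead.center, pose)
        records.append(ReportRecord(
            name="asf", units="mm",
            value={"width_x_mm": ax.width_at_half_max(),
                   "width_y_mm": ay.width_at_half_max()},
            provenance={"bead_center_xyz_mm": list(bead.center),
                        "convention": "top ASF(x), bottom ASF(y)"}))

    run("asf", _asf)

    def _mtf():
        from .geometry import bead_positions
        from .resolution import average_mtf, extract_psf, mtf_from_psf
        zs = vol.z_positions
        curves_x, curves_y = [], []
        for ramp in geometry.ramps:
            for p in bead_positions(ramp):
                p_img = pose.to_image(p)
                # headline MTF: beads within 0.5 mm of an in-focus plane
                if np.min(np.abs(zs - p_img[2])) > 0.5:
                    continue
                try:
                    patch = extract_psf(vol, p, pose)
                except ValueError:
                    continue
                cx, cy = mtf_from_psf(
                    patch, deconvolve_bead=config.deconvolve_bead,
                    bead_diameter_mm=ramp.bead_diameter,
                    eps=config.deconvolution_eps)
                curves_x.append(cx)
                curves_y.append(cy)
        if not curves_x:
            raise ValueError("no in-focus bead yielded a usable PSF")
        mx = average_mtf(curves_x)
        my = average_mtf(curves_y)
        f50x = float(np.interp(0.5, mx.modulation[::-1], mx.frequency[::-1]))
        f50y = float(np.interp(0.5, my.modulation[::-1], my.frequency[::-1]))
        records.append(ReportRecord(
            name="mtf", units="cycles/mm",
            value={"f50_x": f50x, "f50_y": f50y},
            provenance={"n_beads": len(curves_x),
                        "deconvolved": config.deconvolve_bead,
                        "label": "FT-of-PSF MTF"}))

    run("mtf", _mtf)

    def _uniformity():
        from .uniformity import global_uniformity, regional_uniformity
        k_mid = vol.shape[0] // 2
        gu, stats = global_uniformity(vol, k_mid, pose, geometry)
        reg = regional_uniformity(vol, pose, geometry)
        records.append(ReportRecord(
            name="uniformity/global", value=gu, units="percent",
            provenance={"slice_index": k_mid,
                        "roi_means": [s.mean for s in stats],
                        "denominator": "grand mean of the five ROI means"}))
        for label, series in reg.items():
            records.append(ReportRecord(
                name=f"uniformity/regional_{label}",
                value={"mean": float(np.mean([s.mean for s in series])),
                       "sd": float(np.mean([s.sd for s in series]))},
                units="pixel_value",
                provenance={"center_xy_mm": list(
                    {"anterior": (0.0, 78.0)}.get(label, (0, 0))),
                    "n_slices": len(series)}))

    run("uniformity", _uniformity)

    def _snr_cnr():
        from .uniformity import cnr, snr
        k_mid = vol.shape[0] // 2
        s = snr(vol, k_mid, pose, geometry)
        c = cnr(vol, geometry, pose)
        records.append(ReportRecord(
            name="snr", value=s.value, units="ratio",
            provenance={"offset": 0.0, "scale": "raw pixel values"},
            status="flagged" if s.flagged_infinite else "ok"))
        records.append(ReportRecord(
            name="cnr", value=c.value, units="ratio",
            provenance={"net_signal": c.net_signal,
                        "noise_roi": "background (outside square)"}))

    run("snr_cnr", _snr_cnr)

    def _low_contrast():
        from .low_contrast import CD_DIAMETERS, fit_cd_model, \
            sample_circle_means, score_spheres, uniform_region_mask
        readings = score_spheres(vol, geometry, pose,
                                 threshold=config.detection_cnr)
        records.append(ReportRecord(
            name="low_contrast/spheres", units="ratio",
            value=[{"diameter_mm": r.diameter, "cnr": r.cnr_local,
                    "detected": r.detected} for r in readings],
            provenance={"detection_cnr_threshold": config.detection_cnr}))
        mask = uniform_region_mask(vol, geometry, pose)
        k_mid = vol.shape[0] // 2
        img = vol.intensities[k_mid]
        pts = []
        for d in CD_DIAMETERS:
            try:
                sd, n = sample_circle_means(img, vol.spacing[1:], d, 10,
                                            mask, strict=False)
            except ValueError:
                continue
            pts.append((d, sd))
        if len(pts) >= 4:
            fit = fit_cd_model(pts)
            records.append(ReportRecord(
                name="low_contrast/cd_model", value=fit.k, units="pixel_value*mm",
                provenance={"points": pts,
                            "relative_residual": fit.relative_residual,
                            "model": "SD_of_circle_means = k / diameter"},
                status="flagged" if fit.poor_fit else "ok"))

    run("low_contrast", _low_contrast)

    return PipelineResult(records=records, errors=errors,
                          pose=pose if config.is_enabled("positioning")
                          else None)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read the input volume, run all enabled analyses, write the report."""
    vol = read_volume(config.input_path, config.input_format)
    geometry = _load_geometry(config)
    result = analyze_volume(vol, geometry, config)
    header = {
        "software": "tomoqa",
        "version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "geometry_schema_version": geometry.schema_version,
        "acquired_at": vol.metadata.get("acquired_at"),
        "input_metadata": {k: v for k, v in vol.metadata.items()
                           if isinstance(v, (int, float, str))},
    }
    out_dir = Path(config.output_dir)
    result.report_paths = write_report(result.records, out_dir, header=header)
    return result
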