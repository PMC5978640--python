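"""Uniformity, SNR, CNR and the noise-vs-mAs power law.

Regional uniformity: two large (10 mm radius) ROIs in anterior and
lateral positions, means and SDs per slice across z.  Global uniformity:
five 5 mm-radius ROIs in one slice; the metric is the maximum absolute
difference between ROI means expressed as a percentage of the grand mean
(pixel-value scales are not normalised across tomosynthesis systems, so
only relative measures are portable).

SNR is net signal over a uniform region divided by the noise SD of a
neighbouring region; CNR is the net signal over the aluminium square
divided by the background noise SD, with noise measured in the
background (not inside the square) to avoid contrast-dependent noise.
The noise SD follows an approximate square-root dependence on mAs,
fitted as SD = a * mAs^b by least squares in log-log space.

ROI placements default to positions in the uniform band of the default
geometry and are verified to stay clear of every test-object footprint
dilated by a safety margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import PhantomGeometry, footprint_distance, object_footprints
from .positioning import PoseEstimate, identity_pose
from .volume import ReconVolume

__all__ = ["ROIStats", "NoiseFit", "regional_uniformity",
           "global_uniformity", "snr", "cnr", "fit_noise_vs_mas",
           "check_roi_clear", "REGIONAL_ROIS", "GLOBAL_ROIS",
           "SNR_SIGNAL_ROI", "SNR_NOISE_ROI", "CNR_BACKGROUND_ROI"]

#: default ROI centres (x, y in mm) in the uniform band of the default
#: geometry; figure-derived, approximate, configurable per call
REGIONAL_ROIS = {"anterior": (0.0, 78.0), "lateral": (-15.0, 66.0)}
REGIONAL_RADIUS = 10.0
GLOBAL_ROIS = ((-18.0, 70.0), (10.0, 70.0), (-18.0, 82.0), (10.0, 82.0),
               (-4.0, 76.0))
GLOBAL_RADIUS = 5.0
SNR_SIGNAL_ROI = (0.0, 66.0)
SNR_NOISE_ROI = (0.0, 74.0)
SNR_ROI_RADIUS = 5.0
CNR_BACKGROUND_ROI = (0.0, 39.5)
CNR_BACKGROUND_RADIUS = 1.5

OBJECT_CLEARANCE_MM = 2.0


@dataclass
class ROIStats:
    mean: float
    sd: float
    pixel_count: int
    center: tuple[float, float, float]  # xyz mm
    radius: float  # mm
    slice_index: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.pixel_count <= 0:
            raise ValueError("ROI contains no pixels")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass
class NoiseFit:
    amplitude: float  # a in SD = a * mAs^b
    exponent: float  # b
    residual: float  # RMS residual of log SD

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("fit amplitude must be positive")

    def predict(self, mas: float) -> float:
        return self.amplitude * mas ** self.exponent


def check_roi_clear(geometry: PhantomGeometry, center_xy, radius: float,
                    clearance: float = OBJECT_CLEARANCE_MM) -> None:
    """Raise if a disc ROI intersects any test-object footprint (dilated)."""
    c = np.asarray(center_xy, dtype=float)
    for name, kind, pc, params in object_footprints(geometry):
        if footprint_distance(c, kind, pc, params) < radius + clearance:
            raise ValueError(
                f"ROI at {tuple(c)} r={radius} overlaps footprint of "
                f"{name} (centre {tuple(np.round(pc, 1))} "
                f"+ {clearance} mm clearance)")


def _disc_mask(vol: ReconVolume, center_xy, radius: float) -> np.ndarray:
    xs = vol.x_positions
    ys = vol.y_positions
    m = ((xs[None, :] - center_xy[0]) ** 2
         + (ys[:, None] - center_xy[1]) ** 2) <= radius ** 2
    if not m.any():
        raise ValueError(f"ROI at {tuple(center_xy)} lies outside the field")
    return m


def _roi_stats(vol: ReconVolume, k: int, center_xy, radius: float,
               label: str = "") -> ROIStats:
    m = _disc_mask(vol, center_xy, radius)
    vals = vol.intensities[k][m]
    return ROIStats(float(vals.mean()), float(vals.std(ddof=1)),
                    int(vals.size),
                    (center_xy[0], center_xy[1], float(vol.z_positions[k])),
                    radius, k, label=label)


def regional_uniformity(vol: ReconVolume, pose: PoseEstimate | None = None,
                        geometry: PhantomGeometry | None = None,
                        rois: dict | None = None,
                        radius: float = REGIONAL_RADIUS
                        ) -> dict[str, list[ROIStats]]:
    """Per-slice mean/SD for the large anterior and lateral ROIs.

    ROI centres are pose-corrected phantom coordinates; if a geometry is
    given, placement is verified against all object footprints first.
    """
    if pose is None:
        pose = identity_pose(geometry)
    rois = rois or REGIONAL_ROIS
    out: dict[str, list[ROIStats]] = {}
    for label, (x, y) in rois.items():
        if geometry is not None:
            check_roi_clear(geometry, (x, y), radius)
        cx, cy, _ = pose.to_image(np.array([x, y, 0.0]))
        out[label] = [_roi_stats(vol, k, (cx, cy), radius, label)
                      for k in range(vol.shape[0])]
    return out


def global_uniformity(vol: ReconVolume, slice_index: int,
                      pose: PoseEstimate | None = None,
                      geometry: PhantomGeometry | None = None,
                      rois=GLOBAL_ROIS, radius: float = GLOBAL_RADIUS
                      ) -> tuple[float, list[ROIStats]]:
    """Global uniformity of one slice, percent.

    100 x (max absolute difference between the five ROI means) / (grand
    mean of the five ROI means).  Returns the percent value and the
    per-ROI statistics.
    """
    if pose is None:
        pose = identity_pose(geometry)
    stats = []
    for i, (x, y) in enumerate(rois):
        if geometry is not None:
            check_roi_clear(geometry, (x, y), radius)
        cx, cy, _ = pose.to_image(np.array([x, y, 0.0]))
        stats.append(_roi_stats(vol, slice_index, (cx, cy), radius,
                                f"roi{i}"))
    means = np.array([s.mean for s in stats])
    grand = means.mean()
    if grand == 0:
        raise ValueError("grand mean is zero; percent scale undefined")
    value = 100.0 * (means.max() - means.min()) / abs(grand)
    return float(value), stats


@dataclass
class SNRResult:
    value: float  # may be inf for a noiseless input
    flagged_infinite: bool
    signal: ROIStats
    noise: ROIStats


def snr(vol: ReconVolume, slice_index: int,
        pose: PoseEstimate | None = None,
        geometry: PhantomGeometry | None = None,
        signal_roi=SNR_SIGNAL_ROI, noise_roi=SNR_NOISE_ROI,
        radius: float = SNR_ROI_RADIUS, offset: float = 0.0) -> SNRResult:
    """Signal-to-noise ratio: (mean - offset) / SD of a neighbouring ROI.

    The offset is zero by default (raw pixel scale, recorded in
    provenance); a vendor-specific rescale offset can be supplied.
    """
    if pose is None:
        pose = identity_pose(geometry)
    for c in (signal_roi, noise_roi):
        if geometry is not None:
            check_roi_clear(geometry, c, radius)
    sx, sy, _ = pose.to_image(np.array([*signal_roi, 0.0]))
    nx_, ny_, _ = pose.to_image(np.array([*noise_roi, 0.0]))
    sig = _roi_stats(vol, slice_index, (sx, sy), radius, "signal")
    noi = _roi_stats(vol, slice_index, (nx_, ny_), radius, "noise")
    if noi.sd == 0:
        return SNRResult(math.inf, True, sig, noi)
    return SNRResult((sig.mean - offset) / noi.sd, False, sig, noi)


@dataclass
class CNRResult:
    value: float
    net_signal: float
    al_square: ROIStats
    background: ROIStats


def cnr(vol: ReconVolume, geometry: PhantomGeometry,
        pose: PoseEstimate | None = None, inset_mm: float = 2.0,
        background_roi=CNR_BACKGROUND_ROI,
        background_radius: float = CNR_BACKGROUND_RADIUS) -> CNRResult:
    """Contrast-to-noise ratio over the aluminium square.

    Net signal = mean inside the square (inset from its edges) minus the
    mean of an adjacent background ROI, divided by the background SD, on
    the square's in-focus slice.
    """
    if geometry.al_square is None:
        raise ValueError("geometry defines no aluminium square")
    if pose is None:
        pose = identity_pose(geometry)
    b = geometry.al_square
    c_img = pose.to_image(np.asarray(b.center))
    half_x = b.size[0] / 2.0 - inset_mm
    half_y = b.size[1] / 2.0 - inset_mm
    if half_x <= 0 or half_y <= 0:
        raise ValueError("inset leaves no pixels inside the square")
    xs = vol.x_positions
    ys = vol.y_positions
    m_sq = ((np.abs(xs[None, :] - c_img[0]) <= half_x)
            & (np.abs(ys[:, None] - c_img[1]) <= half_y))
    bx, by, _ = pose.to_image(np.array([*background_roi, b.center[2]]))
    m_bg = _disc_mask(vol, (bx, by), background_radius)

    # in-focus slice: maximal square-vs-background contrast
    k_range = [k for k, z in enumerate(vol.z_positions)
               if abs(z - c_img[2]) <= b.size[2]]
    if not k_range:
        raise ValueError("aluminium square not located: no slices near "
                         "its nominal z")
    contr = [vol.intensities[k][m_sq].mean() - vol.intensities[k][m_bg].mean()
             for k in k_range]
    k = k_range[int(np.argmax(contr))]

    sq = vol.intensities[k][m_sq]
    bg = vol.intensities[k][m_bg]
    sq_stats = ROIStats(float(sq.mean()), float(sq.std(ddof=1)), sq.size,
                        tuple(c_img), half_x, k, "al_square")
    bg_stats = ROIStats(float(bg.mean()), float(bg.std(ddof=1)), bg.size,
                        (bx, by, float(vol.z_positions[k])),
                        background_radius, k, "background")
    net = sq_stats.mean - bg_stats.mean
    if bg_stats.sd == 0:
        # noiseless input: CNR is 0 for equal means, infinite otherwise
        value = math.inf if net > 0 else 0.0
        return CNRResult(value, net, sq_stats, bg_stats)
    return CNRResult(net / bg_stats.sd, net, sq_stats, bg_stats)


def fit_noise_vs_mas(points: list[tuple[float, float]]) -> NoiseFit:
    """Fit SD = a * mAs^b by least squares on log SD vs log mAs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (mAs, SD) pairs")
    mas, sd = pts[:, 0], pts[:, 1]
    if len(np.unique(mas)) < 3:
        raise ValueError("need at least 3 distinct mAs values")
    if np.any(mas <= 0) or np.any(sd <= 0):
        raise ValueError("mAs and SD must be positive")
    b, log_a = np.polyfit(np.log(mas), np.log(sd), 1)
    resid = np.log(sd) - (log_a + b * np.log(mas))
    return NoiseFit(amplitude=float(np.exp(log_a)), exponent=float(b),
                    residual=float(np.sqrt(np.mean(resid ** 2))))
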