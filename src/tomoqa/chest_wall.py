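"""Chest-wall offset (missing tissue) from the stair-step gauges.

Each of the four gauges has 12 steps in 0.5 mm increments rising into
the phantom from the chest wall; the depth of tissue lost at the wall is
the full 6 mm gauge extent minus the visible extent.  Visibility is
decided per step by a contrast-to-noise criterion (step mean above local
background by k background-SDs, k = 2 by default) — an automated stand-in
for the observer step counting the measurement was designed around —
counting contiguously from the deepest step toward the wall, and the
visible extent is quantised to whole steps to match the counting
protocol.  A sub-step interpolated estimate is reported separately as
informational.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import StepGauge
from .positioning import PoseEstimate
from .volume import ReconVolume

__all__ = ["GaugeReading", "measure_gauge", "missing_tissue_from_visible"]

#: minimum in-field fraction for a step to be considered measurable
MIN_STEP_FRACTION = 0.5


@dataclass
class GaugeReading:
    gauge_id: str
    visible_extent: float  # mm
    visible_steps: int
    missing_tissue: float  # mm
    missing_tissue_interpolated: float  # informational sub-step estimate
    slice_index: int
    flagged: bool = False
    note: str = ""


def missing_tissue_from_visible(visible_extent: float,
                                gauge: StepGauge) -> float:
    """Missing tissue (mm) = full gauge extent - visible extent."""
    full = gauge.full_extent
    if not 0.0 <= visible_extent <= full + 1e-9:
        raise ValueError(
            f"visible extent {visible_extent} mm outside [0, {full}] mm")
    return full - visible_extent


def _gauge_columns(vol: ReconVolume, gauge: StepGauge, pose: PoseEstimate,
                   x_inset: float = 0.4):
    """Column index range covering the gauge width (inset from the edges)."""
    half = gauge.width / 2.0 - x_inset
    center = pose.to_image(np.array(
        [gauge.lateral_position, gauge.full_extent / 2.0, gauge.z_center]))
    xs = vol.x_positions
    mask = np.abs(xs - center[0]) <= half
    return np.nonzero(mask)[0], center


def measure_gauge(vol: ReconVolume, gauge: StepGauge,
                  pose: PoseEstimate | None = None,
                  k: float = 2.0) -> GaugeReading:
    """Measure one stair-step gauge.

    The measurement slice is the slice of maximal gauge contrast +/- one
    slice, averaged.  A step is visible when its in-field fraction is at
    least 0.5 and its mean signal exceeds the local background (a strip
    beside the gauge) by ``k`` background SDs.
    """
    if pose is None:
        from .positioning import identity_pose
        pose = identity_pose()
    cols, center = _gauge_columns(vol, gauge, pose)
    flagged = False
    note = ""
    if len(cols) == 0:
        raise ValueError(f"{gauge.gauge_id}: gauge not inside imaged field")

    # background strip beside the gauge, same depth range
    dz, dy, dx = vol.spacing
    xs = vol.x_positions
    bg_off = gauge.width / 2.0 + 1.0
    bg_cols = np.nonzero((np.abs(xs - (center[0] + bg_off * 2)) <= 1.0)
                         | (np.abs(xs - (center[0] - bg_off * 2)) <= 1.0))[0]
    if len(bg_cols) == 0:
        flagged = True
        note = "background strip clipped by volume boundary"
        bg_cols = cols  # degenerate fallback

    ys = vol.y_positions
    rows_all = np.nonzero((ys >= 0.0) & (ys <= gauge.full_extent))[0]
    if len(rows_all) == 0:
        # whole gauge outside the field: everything is missing
        return GaugeReading(gauge.gauge_id, 0.0, 0, gauge.full_extent,
                            gauge.full_extent, 0, flagged=True,
                            note="entire gauge outside imaged field")

    # slice of maximal gauge contrast, averaged with its neighbours
    region = vol.intensities[:, rows_all[0]:rows_all[-1] + 1, cols]
    bg_region = vol.intensities[:, rows_all[0]:rows_all[-1] + 1, bg_cols]
    contrast = region.mean(axis=(1, 2)) - bg_region.mean(axis=(1, 2))
    k_best = int(np.argmax(contrast))
    k0, k1 = max(k_best - 1, 0), min(k_best + 2, vol.shape[0])
    img = vol.intensities[k0:k1, :, :].mean(axis=0)

    bg_vals = img[rows_all[0]:rows_all[-1] + 1][:, bg_cols]
    bg_mean = float(np.mean(bg_vals))
    bg_sd = float(np.std(bg_vals))

    visible = np.zeros(gauge.n_steps, dtype=bool)
    measurable = np.zeros(gauge.n_steps, dtype=bool)
    step_means = np.full(gauge.n_steps, np.nan)
    for n in range(gauge.n_steps):
        y0, y1 = gauge.step_y_interval(n)
        rows = np.nonzero((ys >= y0) & (ys < y1))[0]
        frac = len(rows) * dy / gauge.step_increment
        if frac < MIN_STEP_FRACTION:
            continue
        measurable[n] = True
        m = float(img[rows][:, cols].mean())
        step_means[n] = m
        visible[n] = m > bg_mean + k * bg_sd

    # count contiguous visible steps from the deepest step toward the wall
    count = 0
    for n in range(gauge.n_steps - 1, -1, -1):
        if visible[n]:
            count += 1
        else:
            break
    visible_extent = count * gauge.step_increment
    missing = missing_tissue_from_visible(visible_extent, gauge)

    # informational sub-step estimate: first y where the gauge column
    # profile crosses half of its plateau contrast
    prof_rows = rows_all
    prof = img[prof_rows][:, cols].mean(axis=1) - bg_mean
    plateau = np.median(prof[prof > 0.5 * prof.max()]) if prof.max() > 0 else 0.0
    interp = gauge.full_extent
    if plateau > 0:
        above = prof >= 0.5 * plateau
        if np.any(above):
            j = int(np.argmax(above))
            yj = ys[prof_rows[j]]
            if j == 0:
                interp = max(0.0, float(ys[prof_rows[0]]) - dy / 2.0)
            else:
                y_prev = ys[prof_rows[j - 1]]
                f = (0.5 * plateau - prof[j - 1]) / (prof[j] - prof[j - 1])
                interp = float(y_prev + f * (yj - y_prev))
    interp = float(np.clip(interp, 0.0, gauge.full_extent))

    if not np.all(measurable):
        flagged = True
        if not note:
            note = "gauge partially clipped by volume boundary"
    return GaugeReading(gauge.gauge_id, visible_extent, count, missing,
                        interp, k_best, flagged=flagged, note=note)
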