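"""Slice sensitivity profile, slice width and z-axis geometry.

The folded bead ramps project through-plane (z) depth onto the in-plane
grid: each 0.18 mm bead sits 0.25 mm above its neighbour, so the
intensities of the ramp beads within one reconstructed slice sample the
slice sensitivity profile SSP(z) at 0.25 mm resolution.  Each SSP is
sampled in-plane by taking the maximum intensity over the rows containing
each bead, mapping the samples to z through the geometry, background
subtracting and peak normalising; a smoothing spline through the peak
values gives the continuous SSP, whose full width at half maximum is the
slice width.  The bead's own 0.18 mm size is negligible against 1-5 mm
slice widths and is not deconvolved here.

The three 5 mm aluminium beads, nominally spaced 10 mm apart in z, give
through-slice profiles whose fitted peak positions measure z-axis
geometry; in-plane profiles through the same beads across the slice set
give the artifact spread functions ASF(x) and ASF(y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import gaussian_filter

from .geometry import BeadRamp, PhantomGeometry, bead_positions
from .positioning import PoseEstimate, identity_pose
from .volume import ReconVolume

__all__ = ["SSPCurve", "ASFCurve", "extract_ssp", "fwhm",
           "slice_incrementation", "SliceIncrementResult", "z_bead_spacing",
           "asf"]

#: minimum number of resolvable bead peaks for a valid SSP
MIN_PEAKS = 5


@dataclass
class SSPCurve:
    """A sampled slice sensitivity profile (peak normalised to 1)."""

    z: np.ndarray  # mm, strictly increasing (fine grid)
    sensitivity: np.ndarray  # normalised, peak 1
    source: str  # ramp id + slice index
    raw_z: np.ndarray = field(default=None, repr=False)
    raw_sensitivity: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z samples must be strictly increasing")

    @property
    def peak_z(self) -> float:
        return float(self.z[np.argmax(self.sensitivity)])

    @property
    def fwhm(self) -> float:
        return fwhm(self)


@dataclass
class ASFCurve:
    """In-plane artifact spread profile through a bead (peak normalised)."""

    axis: str  # "x" | "y"
    offset: np.ndarray  # mm, symmetric about 0
    response: np.ndarray  # normalised, peak 1
    source: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        self.offset = np.asarray(self.offset, dtype=float)
        self.response = np.asarray(self.response, dtype=float)

    def width_at_half_max(self) -> float:
        """Half-maximum width with sub-sample linear interpolation."""
        r = self.response
        half = 0.5 * r.max()
        idx = np.nonzero(r >= half)[0]
        i0, i1 = idx[0], idx[-1]
        left = self.offset[i0]
        if i0 > 0:
            f = (half - r[i0 - 1]) / (r[i0] - r[i0 - 1])
            left = self.offset[i0 - 1] + f * (self.offset[i0]
                                              - self.offset[i0 - 1])
        right = self.offset[i1]
        if i1 < len(r) - 1:
            f = (half - r[i1 + 1]) / (r[i1] - r[i1 + 1])
            right = self.offset[i1 + 1] - f * (self.offset[i1 + 1]
                                               - self.offset[i1])
        return float(right - left)


def _window_max(img: np.ndarray, iy: float, ix: float, hy: int, hx: int
                ) -> float:
    ny, nx = img.shape
    y0, y1 = max(int(round(iy)) - hy, 0), min(int(round(iy)) + hy + 1, ny)
    x0, x1 = max(int(round(ix)) - hx, 0), min(int(round(ix)) + hx + 1, nx)
    if y0 >= y1 or x0 >= x1:
        return np.nan
    return float(img[y0:y1, x0:x1].max())


def _ramp_background(vol: ReconVolume, ramp: BeadRamp, pose: PoseEstimate,
                     slice_index: int, win: tuple[int, int]
                     ) -> tuple[float, float]:
    """Background statistics of a strip laterally adjacent to the ramp.

    The SSP samples are window *maxima*, a statistic with a noise-
    dependent positive offset; the background is therefore estimated with
    the same statistic (maxima over same-shaped tiles of the strip), so
    the subtraction cancels the offset in expectation.  Returns (median,
    SD) of the tile maxima.
    """
    pts = pose.to_image(bead_positions(ramp))
    ys = vol.y_positions
    xs = vol.x_positions
    rows = np.nonzero((ys >= pts[:, 1].min() - 1.0)
                      & (ys <= pts[:, 1].max() + 1.0))[0]
    # strip on the phantom-interior side of the ramp, clear of the
    # chest-wall gauges and markers
    x_off = pts[:, 0].mean() - np.sign(pts[:, 0].mean() + 1e-9) * 3.0
    cols = np.nonzero(np.abs(xs - x_off) <= 1.5)[0]
    if len(cols) == 0:
        cols = np.nonzero(np.abs(xs - (pts[:, 0].mean() - 3.0)) <= 1.5)[0]
    strip = gaussian_filter(
        vol.intensities[slice_index][np.ix_(rows, cols)].astype(np.float64),
        sigma=1.0)
    wy, wx = win
    ty = (strip.shape[0] // wy) * wy
    tx = (strip.shape[1] // wx) * wx
    if ty == 0 or tx == 0:
        return float(np.median(strip)), float(np.std(strip))
    tiles = strip[:ty, :tx].reshape(ty // wy, wy, tx // wx, wx)
    maxima = tiles.max(axis=(1, 3)).ravel()
    return float(np.median(maxima)), float(np.std(maxima))


def extract_ssp(vol: ReconVolume, ramp: BeadRamp, slice_index: int,
                pose: PoseEstimate | None = None,
                smoothing: float | None = None) -> SSPCurve:
    """Extract the SSP sampled by one folded ramp on one slice.

    Per bead, the maximum intensity over the rows/columns containing the
    bead is taken, mapped to the bead's z, background subtracted and peak
    normalised; a smoothing cubic spline (smoothing factor tied to the
    estimated noise SD unless given) yields the continuous curve on a
    0.05 mm grid.
    """
    if pose is None:
        pose = identity_pose()
    pts = pose.to_image(bead_positions(ramp))
    order = np.argsort(pts[:, 2])
    pts = pts[order]
    # light in-plane smoothing before peak sampling: every bead peak is
    # scaled by the same factor, leaving the normalised SSP shape
    # unchanged while suppressing the noise entering the window maxima
    img = gaussian_filter(vol.intensities[slice_index].astype(np.float64),
                          sigma=1.0)
    dz, dy, dx = vol.spacing
    hy = max(int(round(0.3 / dy)), 1)
    hx = max(int(round(0.3 / dx)), 1)
    vals = np.empty(len(pts))
    for i, p in enumerate(pts):
        _, iy, ix = vol.world_to_index(p)
        vals[i] = _window_max(img, iy, ix, hy, hx)
    ok = np.isfinite(vals)
    bg, bg_sd = _ramp_background(vol, ramp, pose, slice_index,
                                 (2 * hy + 1, 2 * hx + 1))
    sig = vals[ok] - bg
    zs = pts[ok, 2]
    resolvable = sig > 5.0 * bg_sd
    if resolvable.sum() < MIN_PEAKS:
        raise ValueError(
            f"only {int(resolvable.sum())} resolvable bead peaks on slice "
            f"{slice_index}; need at least {MIN_PEAKS}")
    peak = sig.max()
    norm = sig / peak
    if smoothing is None:
        sigma_rel = bg_sd / peak  # relative per-sample noise
        smoothing = len(norm) * sigma_rel ** 2
    # guard against duplicate z (should not happen for a valid ramp)
    zu, idx = np.unique(zs, return_index=True)
    spline = UnivariateSpline(zu, norm[idx], k=3, s=smoothing)
    zf = np.arange(zu[0], zu[-1] + 1e-9, 0.05)
    sf = spline(zf)
    sf = sf / sf.max()
    return SSPCurve(z=zf, sensitivity=sf,
                    source=f"{ramp.ramp_id}/slice{slice_index}",
                    raw_z=zs, raw_sensitivity=norm)


def fwhm(curve: SSPCurve) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    z = curve.z
    v = curve.sensitivity
    ipk = int(np.argmax(v))
    half = 0.5 * v[ipk]

    def _cross(side: str) -> float:
        if side == "left":
            seg = np.nonzero(v[:ipk + 1] < half)[0]
            if len(seg) == 0:
                raise ValueError("no half-maximum crossing left of the peak "
                                 "(truncated profile)")
            j = seg[-1]
            f = (half - v[j]) / (v[j + 1] - v[j])
            return z[j] + f * (z[j + 1] - z[j])
        seg = np.nonzero(v[ipk:] < half)[0]
        if len(seg) == 0:
            raise ValueError("no half-maximum crossing right of the peak "
                             "(truncated profile)")
        j = ipk + seg[0] - 1
        f = (half - v[j]) / (v[j + 1] - v[j])
        return z[j] + f * (z[j + 1] - z[j])

    return float(_cross("right") - _cross("left"))


def slice_width(vol: ReconVolume, ramp: BeadRamp,
                pose: PoseEstimate | None = None,
                n_slices: int = 5) -> float:
    """Volume-level slice width: mean SSP FWHM over the central slices.

    SSPs are extracted on the ``n_slices`` slices nearest the ramp's
    z-centre (where the profile is fully sampled by the folded set) and
    their FWHMs averaged; slices whose profile is truncated are skipped.
    """
    if pose is None:
        pose = identity_pose()
    pts = pose.to_image(bead_positions(ramp))
    zc = 0.5 * (pts[:, 2].min() + pts[:, 2].max())
    k_mid = vol.slice_nearest(zc)
    widths = []
    for k in range(k_mid - n_slices // 2, k_mid - n_slices // 2 + n_slices):
        if not 0 <= k < vol.shape[0]:
            continue
        try:
            widths.append(fwhm(extract_ssp(vol, ramp, k, pose)))
        except ValueError:
            continue
    if not widths:
        raise ValueError("no slice yielded a measurable SSP")
    return float(np.mean(widths))


@dataclass
class SliceIncrementResult:
    mean_mm: float
    differences: np.ndarray  # consecutive peak-z differences
    outliers: np.ndarray  # bool per difference
    slice_indices: list


def slice_incrementation(vol: ReconVolume, ramp: BeadRamp,
                         pose: PoseEstimate | None = None,
                         slice_indices: list[int] | None = None
                         ) -> SliceIncrementResult:
    """Mean difference of SSP peak z between consecutive slices.

    Uses the slices whose centres fall well inside the ramp's z span, so
    every SSP peak is interior.  A consecutive difference below a quarter
    of (or 4x above) the median is flagged as an increment outlier.
    """
    if pose is None:
        pose = identity_pose()
    if slice_indices is None:
        pts = pose.to_image(bead_positions(ramp))
        zlo, zhi = pts[:, 2].min() + 1.5, pts[:, 2].max() - 1.5
        slice_indices = [k for k, z in enumerate(vol.z_positions)
                         if zlo <= z <= zhi]
    if len(slice_indices) < 3:
        raise ValueError("need at least 3 slices with extractable SSPs")
    peaks = []
    for k in slice_indices:
        peaks.append(extract_ssp(vol, ramp, k, pose).peak_z)
    diffs = np.diff(peaks)
    med = np.median(diffs)
    outliers = (diffs < 0.25 * med) | (diffs > 4.0 * med) if med > 0 \
        else np.ones_like(diffs, dtype=bool)
    good = diffs[~outliers]
    mean = float(np.mean(good)) if len(good) else float("nan")
    return SliceIncrementResult(mean_mm=mean, differences=diffs,
                                outliers=outliers,
                                slice_indices=list(slice_indices))


def _bead_profile(vol: ReconVolume, center, roi_radius: float = 1.5
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-in-disc through-slice profile for a bead at ``center`` (xyz)."""
    xs = vol.x_positions
    ys = vol.y_positions
    disc = ((xs[None, :] - center[0]) ** 2
            + (ys[:, None] - center[1]) ** 2) <= roi_radius ** 2
    if not disc.any():
        raise ValueError("bead ROI outside imaged field")
    prof = vol.intensities[:, disc].mean(axis=1)
    return vol.z_positions, prof


def _profile_peak_z(zs: np.ndarray, prof: np.ndarray) -> float:
    """Peak z of a through-slice bead profile.

    A thick bead convolved with the slice profile gives a symmetric dome
    that may saturate into a plateau, so the peak is located as the
    midpoint of the interpolated half-maximum crossings (exact for any
    symmetric profile and robust to noise on a flat top) after a spline
    fit of the normalised profile.
    """
    bg = np.percentile(prof, 20)
    sig = prof - bg
    if sig.max() <= 0:
        raise ValueError("no signal in bead profile")
    w = sig / sig.max()
    spline = UnivariateSpline(zs, w, k=3, s=max(len(w) * 1e-4, 1e-6))
    zf = np.arange(zs[0], zs[-1] + 1e-9, 0.02)
    wf = spline(zf)
    wf /= wf.max()
    curve = SSPCurve(z=zf, sensitivity=wf, source="z-bead profile")
    ipk = int(np.argmax(wf))
    try:
        width = fwhm(curve)
        # recover the left crossing to form the midpoint
        half = 0.5
        left_idx = np.nonzero(wf[:ipk + 1] < half)[0]
        j = left_idx[-1]
        f = (half - wf[j]) / (wf[j + 1] - wf[j])
        left = zf[j] + f * (zf[j + 1] - zf[j])
        return float(left + width / 2.0)
    except ValueError:
        # profile truncated on one side: fall back to the spline argmax
        return float(zf[ipk])


def z_bead_spacing(vol: ReconVolume, geometry: PhantomGeometry,
                   pose: PoseEstimate | None = None) -> np.ndarray:
    """Consecutive z spacings (mm) between the aluminium z-geometry beads.

    Per bead, the through-slice profile (mean over a bead-centred disc) is
    fitted with a spline and the spacing is the difference of consecutive
    fitted peak positions, ordered by nominal z.
    """
    if pose is None:
        pose = identity_pose(geometry)
    if not geometry.z_beads:
        raise ValueError("geometry defines no z-geometry beads")
    beads = sorted(geometry.z_beads, key=lambda b: b.center[2])
    nominal_z = [b.center[2] for b in beads]
    # beads may share an in-plane position; restrict each profile to a z
    # window that cannot reach the neighbouring bead's peak
    if len(nominal_z) > 1:
        half_win = 0.5 * min(np.diff(nominal_z))
    else:
        half_win = vol.z_positions[-1] - vol.z_positions[0]
    half_win = max(half_win, 2.0 * vol.spacing[0])
    peaks = []
    for i, b in enumerate(beads):
        c = pose.to_image(np.asarray(b.center))
        zs, prof = _bead_profile(vol, c)
        sel = np.abs(zs - c[2]) <= half_win
        zs, prof = zs[sel], prof[sel]
        if len(zs) < 4:
            raise ValueError(f"z-geometry bead {i}: too few slices in window")
        bg = np.percentile(prof, 20)
        noise = np.std(np.sort(prof)[:max(len(prof) // 2, 2)]) + 1e-9
        if prof.max() - bg < 5.0 * noise:
            raise ValueError(f"z-geometry bead {i} not found "
                             f"(no peak above background)")
        peaks.append(_profile_peak_z(zs, prof))
    return np.diff(peaks)


def asf(vol: ReconVolume, bead_center, pose: PoseEstimate | None = None,
        half_width_mm: float = 6.0, source: str = ""
        ) -> tuple[ASFCurve, ASFCurve]:
    """Artifact spread functions ASF(x) and ASF(y) for a high-contrast bead.

    Profiles along x and y through the bead centre are taken on every
    slice spanning the bead and combined by maximum projection, capturing
    how the bead's signal spreads in-plane across the slice set; curves
    are background-subtracted and peak normalised.
    """
    if pose is None:
        pose = identity_pose()
    c = pose.to_image(np.asarray(bead_center))
    dz, dy, dx = vol.spacing
    iz, iy, ix = vol.world_to_index(c)
    nz = vol.shape[0]
    span = max(int(round(4.0 / dz)), 1)
    k0, k1 = max(int(round(iz)) - span, 0), min(int(round(iz)) + span + 1, nz)
    hx = int(round(half_width_mm / dx))
    hy = int(round(half_width_mm / dy))
    iy0, ix0 = int(round(iy)), int(round(ix))
    ny, nx = vol.shape[1:]
    if (ix0 - hx < 0 or ix0 + hx >= nx or iy0 - hy < 0 or iy0 + hy >= ny):
        raise ValueError("ASF profile extends outside the imaged field")
    sub = vol.intensities[k0:k1]
    prof_x = sub[:, iy0, ix0 - hx:ix0 + hx + 1].max(axis=0)
    prof_y = sub[:, iy0 - hy:iy0 + hy + 1, ix0].max(axis=0)
    off_x = (np.arange(-hx, hx + 1)) * dx
    off_y = (np.arange(-hy, hy + 1)) * dy

    def _norm(p):
        bg = np.median(np.concatenate([p[:5], p[-5:]]))
        q = p - bg
        # robust noise scale over the whole profile (the background
        # majority dominates the median absolute deviation)
        noise = 1.4826 * np.median(np.abs(q))
        if q.max() <= 6.0 * noise + 1e-12:
            raise ValueError("bead not found: no peak above background "
                             "along the ASF profile")
        return q / q.max()

    return (ASFCurve("x", off_x, _norm(prof_x), source=source),
            ASFCurve("y", off_y, _norm(prof_y), source=source))
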