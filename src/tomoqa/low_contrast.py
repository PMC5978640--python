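"""Low-contrast sphere conspicuity and the contrast-detail noise model.

Nine low-contrast spheres (0.8-10 mm) probe detectability.  Each sphere
is scored with a disc ROI of matching diameter at its known
(pose-corrected) centre on the in-focus slice against a local background
annulus; detection is threshold-based on the local CNR (net signal over
annulus SD), since detectability is otherwise observer-dependent.

The contrast-detail noise model samples circles of the sphere diameters
from a uniform region: the standard deviation of the circle means grows
as diameter shrinks (fewer pixels per circle), and a single-parameter
hyperbola SD(d) = k / d is fitted to the (diameter, SD-of-means) points.
Circle placement is a deterministic hexagonal packing of non-overlapping
circles inside a user-supplied mask, so results are reproducible without
a random-placement seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PhantomGeometry, footprint_distance, object_footprints
from .positioning import PoseEstimate, identity_pose
from .volume import ReconVolume

__all__ = ["SphereReading", "CDModel", "score_spheres",
           "sample_circle_means", "fit_cd_model", "pack_circles",
           "uniform_region_mask", "CD_DIAMETERS"]

#: diameters used for the contrast-detail fit (mm); the 0.8 mm sphere is
#: excluded by default because too few pixels fall in such circles
CD_DIAMETERS = (10.0, 8.0, 6.0, 4.0, 3.0, 2.0, 1.5, 1.0)

DETECTION_CNR_THRESHOLD = 1.0


@dataclass
class SphereReading:
    diameter: float  # mm
    net_signal: float  # mean in sphere ROI - local background mean
    cnr_local: float
    detected: bool
    slice_index: int
    center: tuple[float, float, float]


@dataclass
class CDModel:
    k: float  # SD_of_means(d) = k / d
    residual: float  # RMS residual
    relative_residual: float  # residual / mean SD
    diameters: tuple

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def predict(self, d) -> np.ndarray:
        return self.k / np.asarray(d, dtype=float)

    @property
    def poor_fit(self) -> bool:
        return self.relative_residual > 0.25


def score_spheres(vol: ReconVolume, geometry: PhantomGeometry,
                  pose: PoseEstimate | None = None,
                  threshold: float = DETECTION_CNR_THRESHOLD
                  ) -> list[SphereReading]:
    """Score every low-contrast sphere on its in-focus slice.

    The background annulus around each sphere excludes pixels inside any
    other object footprint (with 1 mm margin), so densely packed
    neighbours do not bias the local background.
    """
    if pose is None:
        pose = identity_pose(geometry)
    if not geometry.low_contrast_spheres:
        raise ValueError("geometry defines no low-contrast spheres")
    xs = vol.x_positions
    ys = vol.y_positions
    footprints = object_footprints(geometry)
    out = []
    for si, s in enumerate(geometry.low_contrast_spheres):
        c = pose.to_image(np.asarray(s.center))
        if not (xs[0] <= c[0] <= xs[-1] and ys[0] <= c[1] <= ys[-1]):
            raise ValueError(f"sphere {s.diameter} mm centre out of field")
        k = vol.slice_nearest(c[2])
        r = s.diameter / 2.0
        rho2 = (xs[None, :] - c[0]) ** 2 + (ys[:, None] - c[1]) ** 2
        disc = rho2 <= r ** 2
        ann = (rho2 >= (r + 1.0) ** 2) & (rho2 <= (r + 3.0) ** 2)
        # mask out neighbouring objects from the annulus
        ayy, axx = np.nonzero(ann)
        pts = np.column_stack([xs[axx], ys[ayy]])
        keep = np.ones(len(pts), dtype=bool)
        for j, (name, kind, pc, params) in enumerate(footprints):
            if name == "sphere" and j == si:
                continue
            d = np.asarray([footprint_distance(p, kind, pc, params)
                            for p in pts])
            keep &= d > 1.0
        ann_idx = (ayy[keep], axx[keep])
        img = vol.intensities[k]
        bg_vals = img[ann_idx]
        if bg_vals.size < 10:
            raise ValueError(f"background annulus for {s.diameter} mm "
                             "sphere nearly empty")
        net = float(img[disc].mean() - bg_vals.mean())
        sd = float(bg_vals.std(ddof=1))
        cnr_local = net / sd if sd > 0 else np.inf * np.sign(net or 1.0)
        out.append(SphereReading(s.diameter, net, float(cnr_local),
                                 bool(cnr_local >= threshold), k,
                                 tuple(c)))
    return out


def uniform_region_mask(vol: ReconVolume, geometry: PhantomGeometry,
                        pose: PoseEstimate | None = None,
                        clearance: float = 2.0) -> np.ndarray:
    """Boolean in-plane mask of pixels clear of every object footprint.

    This is the sampling region for the contrast-detail circles: the
    uniform area next to the low-contrast spheres, excluding all test
    objects (dilated by ``clearance``) and the field border.
    """
    if pose is None:
        pose = identity_pose(geometry)
    xs = vol.x_positions
    ys = vol.y_positions
    mask = np.ones((len(ys), len(xs)), dtype=bool)
    border = 1.0
    mask[:, xs < xs[0] + border] = False
    mask[:, xs > xs[-1] - border] = False
    mask[ys < ys[0] + border, :] = False
    mask[ys > ys[-1] - border, :] = False
    X, Y = np.meshgrid(xs, ys)
    for name, kind, pc, params in object_footprints(geometry):
        pc_img = pose.to_image(np.array([pc[0], pc[1], 0.0]))[:2]
        if kind == "circle":
            d2 = (X - pc_img[0]) ** 2 + (Y - pc_img[1]) ** 2
            mask &= d2 > (params[0] + clearance) ** 2
        else:
            inside = ((np.abs(X - pc_img[0]) <= params[0] + clearance)
                      & (np.abs(Y - pc_img[1]) <= params[1] + clearance))
            mask &= ~inside
    return mask


def pack_circles(mask: np.ndarray, spacing: tuple[float, float],
                 diameter_mm: float, n_max: int | None = None
                 ) -> list[tuple[float, float]]:
    """Deterministic hexagonal packing of non-overlapping circles.

    Returns pixel-coordinate (row, col) centres of circles of
    ``diameter_mm`` that lie entirely inside ``mask``.  ``spacing`` is
    (dy, dx) mm.
    """
    dy, dx = spacing
    r_px_y = diameter_mm / 2.0 / dy
    r_px_x = diameter_mm / 2.0 / dx
    pitch_x = diameter_mm * 1.05 / dx
    pitch_y = diameter_mm * 1.05 * np.sqrt(3) / 2.0 / dy
    ny, nx = mask.shape
    centers = []
    row = 0
    y = r_px_y + 1
    while y < ny - r_px_y - 1:
        x0 = r_px_x + 1 + (pitch_x / 2.0 if row % 2 else 0.0)
        x = x0
        while x < nx - r_px_x - 1:
            yy, xx = int(round(y)), int(round(x))
            # circle fully inside mask?
            ys_ = np.arange(int(np.floor(y - r_px_y)),
                            int(np.ceil(y + r_px_y)) + 1)
            xs_ = np.arange(int(np.floor(x - r_px_x)),
                            int(np.ceil(x + r_px_x)) + 1)
            sub = ((xs_[None, :] - x) / r_px_x) ** 2 \
                + ((ys_[:, None] - y) / r_px_y) ** 2 <= 1.0
            if mask[np.ix_(ys_, xs_)][sub].all():
                centers.append((y, x))
                if n_max is not None and len(centers) >= n_max:
                    return centers
            x += pitch_x
        y += pitch_y
        row += 1
    return centers


def sample_circle_means(slice_img: np.ndarray, spacing: tuple[float, float],
                        diameter_mm: float, n_samples: int,
                        mask: np.ndarray, strict: bool = True
                        ) -> tuple[float, int]:
    """SD of the means of non-overlapping circles sampled from a region.

    Returns (SD of circle means, number of circles used).  With
    ``strict`` (default) it is an error when fewer than ``n_samples``
    circles fit in the mask; otherwise n is capped by the packing.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    centers = pack_circles(mask, spacing, diameter_mm, n_max=n_samples)
    if len(centers) < n_samples and strict:
        raise ValueError(
            f"only {len(centers)} non-overlapping {diameter_mm} mm circles "
            f"fit in the mask; {n_samples} requested")
    if len(centers) < 2:
        raise ValueError("need at least 2 circles to compute an SD")
    dy, dx = spacing
    means = []
    for (cy, cx) in centers:
        ry = diameter_mm / 2.0 / dy
        rx = diameter_mm / 2.0 / dx
        ys_ = np.arange(int(np.floor(cy - ry)), int(np.ceil(cy + ry)) + 1)
        xs_ = np.arange(int(np.floor(cx - rx)), int(np.ceil(cx + rx)) + 1)
        sub = ((xs_[None, :] - cx) / rx) ** 2 \
            + ((ys_[:, None] - cy) / ry) ** 2 <= 1.0
        means.append(slice_img[np.ix_(ys_, xs_)][sub].mean())
    return float(np.std(means, ddof=1)), len(centers)


def fit_cd_model(points: list[tuple[float, float]]) -> CDModel:
    """Least-squares fit of SD = k / d to (diameter, SD-of-means) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (diameter, SD) pairs")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 diameters for the fit")
    d, sd = pts[:, 0], pts[:, 1]
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    inv = 1.0 / d
    k = float((sd * inv).sum() / (inv * inv).sum())
    resid = sd - k * inv
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return CDModel(k=max(k, 0.0), residual=rms,
                   relative_residual=rms / max(sd.mean(), 1e-12),
                   diameters=tuple(d))
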