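"""Synthetic reconstructed-volume renderer.

Renders the phantom's analytic solids (spheres, boxes, bead ramps) into a
voxel grid under a parameterised acquisition model:

1. pose applied as a rigid rotation about the phantom centre (plus an
   optional in-plane translation) *before* sampling;
2. through-plane convolution with the slice profile, evaluated
   analytically per voxel column (each column's intersection with a
   convex solid is a z-interval, so the profile integral has closed
   form via the profile CDF);
3. in-plane partial volume by 3x supersampling with box averaging,
   followed by the anisotropic in-plane Gaussian blur;
4. additive Gaussian noise with SD scaled by mAs.

Out-of-plane reconstruction streaking is approximated solely by the slice
profile's tails; no projection/reconstruction is simulated, because the
analyses measure profiles rather than reconstruct them.

Every render has a matching :func:`truth_record` giving the ground-truth
object positions (in the posed image frame), slice width and noise SD
against which the analysis modules are validated.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .acquisition import AcquisitionModel, SliceProfile
from .geometry import PhantomGeometry, bead_positions
from .volume import ReconVolume

__all__ = ["render", "render_series", "truth_record"]

SUPERSAMPLE = 3


def _pose_transform(geometry: PhantomGeometry, acq: AcquisitionModel):
    """Return p_img = R (p - c) + c + t as a callable on (n,3) points."""
    R = acq.rotation().as_matrix()
    c = geometry.center
    t = np.array([acq.translation_xy[0], acq.translation_xy[1], 0.0])

    def apply(points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - c) @ R.T + c + t
        return out if np.asarray(points).ndim == 2 else out[0]

    return apply, R, c, t


def _grid(geometry: PhantomGeometry, acq: AcquisitionModel):
    dx = acq.pixel_spacing_xy
    dz = acq.slice_increment
    x0, x1 = geometry.x_range
    y0 = geometry.y_range[0] + acq.chest_wall_offset
    y1 = geometry.y_range[1]
    nx = int(round((x1 - x0) / dx))
    ny = int(round((y1 - y0) / dx))
    nz = int(round(geometry.overall_thickness / dz))
    if nx < 1 or ny < 1 or nz < 1:
        raise ValueError("grid does not cover the phantom bounding box")
    origin = (x0 + dx / 2.0, y0 + dx / 2.0, dz / 2.0)
    return (nx, ny, nz), origin


def _supersampled_patch(origin_xy, dx, ix0, ix1, iy0, iy1, s):
    """Supersampled x/y coordinate vectors for pixel block [iy0:iy1, ix0:ix1]."""
    mx = np.arange(ix0 * s, ix1 * s)
    my = np.arange(iy0 * s, iy1 * s)
    xs = origin_xy[0] - dx / 2.0 + (mx + 0.5) * dx / s
    ys = origin_xy[1] - dx / 2.0 + (my + 0.5) * dx / s
    return xs, ys


def _block_average(a: np.ndarray, s: int) -> np.ndarray:
    ny, nx = a.shape
    return a.reshape(ny // s, s, nx // s, s).mean(axis=(1, 3))


def _clip_range(c, half, lo, n, d):
    i0 = int(np.floor((c - half - lo) / d))
    i1 = int(np.ceil((c + half - lo) / d)) + 1
    return max(i0, 0), min(i1, n)


def _add_sphere(vol, origin, dx, dz, profile, center, radius, amp,
                s=SUPERSAMPLE):
    """Accumulate a sphere's slice-profile-convolved signal into vol."""
    nz, ny, nx = vol.shape
    cx, cy, cz = center
    x_lo = origin[0] - dx / 2.0
    y_lo = origin[1] - dx / 2.0
    ix0, ix1 = _clip_range(cx, radius + dx, x_lo, nx, dx)
    iy0, iy1 = _clip_range(cy, radius + dx, y_lo, ny, dx)
    if ix0 >= ix1 or iy0 >= iy1:
        return
    xs, ys = _supersampled_patch(origin, dx, ix0, ix1, iy0, iy1, s)
    rho2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    h = np.sqrt(np.clip(radius ** 2 - rho2, 0.0, None))
    if not np.any(h > 0):
        return
    z_lo = origin[2] - dz / 2.0
    k0, k1 = _clip_range(cz, radius + profile.support, z_lo, nz, dz)
    for k in range(k0, k1):
        zk = origin[2] + k * dz
        contrib = amp * profile.interval_integral(cz - h, cz + h, zk)
        vol[k, iy0:iy1, ix0:ix1] += _block_average(contrib, s)


def _add_box(vol, origin, dx, dz, profile, R, c, t, center, size, amp,
             s=SUPERSAMPLE):
    """Accumulate a (possibly pose-rotated) box's signal into vol.

    The box is axis-aligned in the phantom frame; a voxel column's
    intersection with it in the image frame is the intersection of three
    slabs linear in z, hence an interval with closed-form profile integral.
    """
    nz, ny, nx = vol.shape
    half = np.asarray(size, dtype=float) / 2.0
    center = np.asarray(center, dtype=float)
    center_img = R @ (center - c) + c + t
    rad = float(np.linalg.norm(half))
    x_lo = origin[0] - dx / 2.0
    y_lo = origin[1] - dx / 2.0
    ix0, ix1 = _clip_range(center_img[0], rad + dx, x_lo, nx, dx)
    iy0, iy1 = _clip_range(center_img[1], rad + dx, y_lo, ny, dx)
    if ix0 >= ix1 or iy0 >= iy1:
        return
    xs, ys = _supersampled_patch(origin, dx, ix0, ix1, iy0, iy1, s)
    X, Y = np.meshgrid(xs, ys)
    # phantom-frame coordinates of the column point at image z = 0, and the
    # direction of increasing image z
    base = np.stack([X - c[0] - t[0], Y - c[1] - t[1],
                     np.full_like(X, -c[2] - t[2])], axis=0)
    Rt = R.T
    u = np.tensordot(Rt, base, axes=1) + c[:, None, None] - center[:, None, None]
    v = Rt[:, 2]
    za = np.full(X.shape, -np.inf)
    zb = np.full(X.shape, np.inf)
    for i in range(3):
        if abs(v[i]) < 1e-12:
            inside = np.abs(u[i]) <= half[i]
            za = np.where(inside, za, np.inf)
            zb = np.where(inside, zb, -np.inf)
        else:
            t0 = (-half[i] - u[i]) / v[i]
            t1 = (half[i] - u[i]) / v[i]
            lo = np.minimum(t0, t1)
            hi = np.maximum(t0, t1)
            za = np.maximum(za, lo)
            zb = np.minimum(zb, hi)
    valid = zb > za
    if not np.any(valid):
        return
    za = np.where(valid, za, 0.0)
    zb = np.where(valid, zb, 0.0)
    z_lo = origin[2] - dz / 2.0
    k0, k1 = _clip_range(center_img[2], rad + profile.support, z_lo, nz, dz)
    for k in range(k0, k1):
        zk = origin[2] + k * dz
        contrib = amp * profile.interval_integral(za, zb, zk)
        vol[k, iy0:iy1, ix0:ix1] += _block_average(contrib, s)


def render(geometry: PhantomGeometry, acq: AcquisitionModel,
           *, with_noise: bool = True, rng: np.random.Generator | None = None
           ) -> ReconVolume:
    """Render a reconstructed volume of the phantom.

    Deterministic for a fixed ``acq.seed``.  The grid is built from the
    geometry's bounding box and the acquisition spacings; a positive
    ``chest_wall_offset`` deliberately truncates the field at the wall.
    """
    (nx, ny, nz), origin = _grid(geometry, acq)
    dx = acq.pixel_spacing_xy
    dz = acq.slice_increment
    profile = acq.profile()
    apply_pose, R, c, t = _pose_transform(geometry, acq)
    bg = acq.background_level

    vol = np.zeros((nz, ny, nx), dtype=np.float32)

    for s in (*geometry.z_beads, *geometry.low_contrast_spheres,
              *geometry.alignment_markers):
        center = apply_pose(np.asarray(s.center))
        _add_sphere(vol, origin, dx, dz, profile, center, s.diameter / 2.0,
                    bg * s.contrast)
    for ramp in geometry.ramps:
        for p in bead_positions(ramp):
            _add_sphere(vol, origin, dx, dz, profile, apply_pose(p),
                        ramp.bead_diameter / 2.0, bg * ramp.contrast)
    if geometry.al_square is not None:
        b = geometry.al_square
        _add_box(vol, origin, dx, dz, profile, R, c, t, b.center, b.size,
                 bg * b.contrast)
    for g in geometry.gauges:
        for n in range(g.n_steps):
            y0, y1 = g.step_y_interval(n)
            center = (g.lateral_position, (y0 + y1) / 2.0, g.z_center)
            _add_box(vol, origin, dx, dz, profile, R, c, t, center,
                     (g.width, g.step_increment, g.thickness), bg * g.contrast)

    sx, sy = acq.inplane_blur
    if sx > 0 or sy > 0:
        gaussian_filter(vol, sigma=(0.0, sy / dx, sx / dx), truncate=4.0,
                        output=vol, mode="nearest")
    vol += bg

    sd = acq.noise_sd()
    if with_noise and sd > 0:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        vol += sd * rng.standard_normal(vol.shape, dtype=np.float32)

    meta = {
        "mAs": acq.mas,
        "nominal_slice_width_mm": acq.nominal_slice_width,
        "slice_increment_mm": dz,
        "pixel_spacing_mm": dx,
        "background_level": bg,
        "noise_sd": sd if with_noise else 0.0,
        "seed": acq.seed,
        "chest_wall_offset_mm": acq.chest_wall_offset,
    }
    return ReconVolume(vol, spacing=(dz, dx, dx),
                       origin=origin, metadata=meta)


def truth_record(geometry: PhantomGeometry, acq: AcquisitionModel) -> dict:
    """Ground-truth record for a render of (geometry, acq).

    All positions are in the posed image frame, i.e. where the objects
    actually are in the rendered volume.
    """
    apply_pose, _, _, _ = _pose_transform(geometry, acq)
    rec = {
        "pose_deg": {"roll": acq.pose[0], "pitch": acq.pose[1],
                     "yaw": acq.pose[2]},
        "translation_xy_mm": list(acq.translation_xy),
        "slice_width_mm": acq.nominal_slice_width,
        "slice_profile": acq.slice_profile,
        "slice_increment_mm": acq.slice_increment,
        "noise_sd": acq.noise_sd(),
        "chest_wall_offset_mm": acq.chest_wall_offset,
        "background_level": acq.background_level,
        "markers_xyz_mm": [list(apply_pose(np.asarray(m.center)))
                           for m in geometry.alignment_markers],
        "z_beads_xyz_mm": [list(apply_pose(np.asarray(b.center)))
                           for b in geometry.z_beads],
        "spheres": [{"diameter_mm": s.diameter, "contrast": s.contrast,
                     "center_xyz_mm": list(apply_pose(np.asarray(s.center)))}
                    for s in geometry.low_contrast_spheres],
        "ramps": {r.ramp_id: [list(p) for p in
                              np.atleast_2d(apply_pose(bead_positions(r)))]
                  for r in geometry.ramps},
    }
    return rec


def render_series(geometry: PhantomGeometry, acq: AcquisitionModel,
                  mas_list: list[float]) -> list[ReconVolume]:
    """Render one volume per mAs with reproducibly derived child seeds."""
    if not mas_list:
        raise ValueError("mas_list must be non-empty")
    if any(m <= 0 for m in mas_list):
        raise ValueError("mAs values must be positive")
    import dataclasses

    out = []
    for i, m in enumerate(mas_list):
        child = dataclasses.replace(acq, mas=float(m),
                                    seed=int(acq.seed) * 1000 + i)
        out.append(render(geometry, child))
    return out
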