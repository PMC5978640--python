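"""Phantom pose estimation from alignment markers.

The phantom carries dedicated high-contrast spherical markers.  Their
sub-voxel centroids are located by intensity-weighted centre of mass and
registered to the known geometry by orthogonal Procrustes (Kabsch),
giving roll, pitch and yaw in a fixed intrinsic z-y-x (yaw-pitch-roll)
convention plus an in-plane translation.  Downstream modules consume the
estimate as a coordinate transform applied to ROI positions; intensities
are never resampled, so noise statistics are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import PhantomGeometry
from .volume import ReconVolume

__all__ = ["PoseEstimate", "locate_markers", "estimate_pose", "identity_pose"]

#: angles beyond this are flagged unreliable (deg)
MAX_RELIABLE_ANGLE = 15.0


@dataclass
class PoseEstimate:
    roll: float  # deg, about x
    pitch: float  # deg, about y
    yaw: float  # deg, about z
    translation: tuple[float, float] = (0.0, 0.0)  # (x, y) mm
    residual_mm: float = 0.0  # RMS registration residual
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rotation centre
    reliable: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("roll", "pitch", "yaw"):
            a = getattr(self, name)
            if not np.isfinite(a):
                raise ValueError(f"{name} must be finite")
            self.reliable.setdefault(name, bool(abs(a) < MAX_RELIABLE_ANGLE))

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.roll, self.pitch, self.yaw)

    def rotation(self) -> Rotation:
        return Rotation.from_euler("ZYX", [self.yaw, self.pitch, self.roll],
                                   degrees=True)

    def to_image(self, points) -> np.ndarray:
        """Map phantom-frame xyz points to their posed image-frame positions."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        t = np.array([self.translation[0], self.translation[1], 0.0])
        out = (p - c) @ self.rotation().as_matrix().T + c + t
        return out if np.asarray(points).ndim == 2 else out[0]


def identity_pose(geometry: PhantomGeometry | None = None) -> PoseEstimate:
    c = tuple(geometry.center) if geometry is not None else (0.0, 0.0, 0.0)
    return PoseEstimate(0.0, 0.0, 0.0, center=c)


def _refine_centroid(vol: ReconVolume, guess_xyz: np.ndarray,
                     box_mm=(4.0, 3.0, 3.0)) -> np.ndarray:
    """Background-subtracted centre of mass in a box around ``guess_xyz``.

    ``box_mm`` is the half-size (z, y, x).  Background is the box-border
    median; negative residuals are clipped so noise does not destabilise
    the centroid.
    """
    iz, iy, ix = vol.world_to_index(guess_xyz)
    dz, dy, dx = vol.spacing
    hz = int(round(box_mm[0] / dz))
    hy = int(round(box_mm[1] / dy))
    hx = int(round(box_mm[2] / dx))
    z0, z1 = int(round(iz)) - hz, int(round(iz)) + hz + 1
    y0, y1 = int(round(iy)) - hy, int(round(iy)) + hy + 1
    x0, x1 = int(round(ix)) - hx, int(round(ix)) + hx + 1
    nz, ny, nx = vol.shape
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1, y1, x1 = min(z1, nz), min(y1, ny), min(x1, nx)
    patch = vol.intensities[z0:z1, y0:y1, x0:x1].astype(np.float64)
    border = np.concatenate([patch[0].ravel(), patch[-1].ravel(),
                             patch[:, 0].ravel(), patch[:, -1].ravel(),
                             patch[:, :, 0].ravel(), patch[:, :, -1].ravel()])
    bg = np.median(border)
    w = np.clip(patch - bg, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("no signal above background at expected marker site")
    gz, gy, gx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    com = np.array([(w * gz).sum(), (w * gy).sum(), (w * gx).sum()]) / total
    return vol.index_to_world(com)


def locate_markers(vol: ReconVolume, geometry: PhantomGeometry,
                   search_radius_mm: float = 8.0,
                   min_snr: float = 5.0) -> np.ndarray:
    """Locate the alignment markers; returns (n, 3) xyz mm, geometry order.

    Each marker is searched for in a box of ``search_radius_mm`` around
    its nominal position (pose perturbations within the reliable range
    stay inside the box); its centroid is the intensity-weighted centre
    of mass after local background subtraction.  A marker whose peak does
    not exceed the local background by ``min_snr`` noise SDs is counted
    missing, and a single missing marker is an error.
    """
    markers = geometry.alignment_markers
    if not markers:
        raise ValueError("geometry defines no alignment markers")
    found, missing = [], []
    dz, dy, dx = vol.spacing
    for i, m in enumerate(markers):
        c = np.asarray(m.center)
        iz, iy, ix = vol.world_to_index(c)
        hz = int(round(search_radius_mm / dz))
        hxy = int(round(search_radius_mm / dx))
        nz, ny, nx = vol.shape
        z0, z1 = max(int(iz) - hz, 0), min(int(iz) + hz + 1, nz)
        y0, y1 = max(int(iy) - hxy, 0), min(int(iy) + hxy + 1, ny)
        x0, x1 = max(int(ix) - hxy, 0), min(int(ix) + hxy + 1, nx)
        box = vol.intensities[z0:z1, y0:y1, x0:x1]
        if box.size == 0:
            missing.append(i)
            continue
        bg = np.median(box)
        noise = np.median(np.abs(box - bg)) * 1.4826 + 1e-12
        peak_idx = np.unravel_index(np.argmax(box), box.shape)
        if box[peak_idx] < bg + min_snr * noise:
            missing.append(i)
            continue
        guess = vol.index_to_world(np.array(peak_idx, dtype=float)
                                   + [z0, y0, x0])
        found.append(_refine_centroid(vol, guess))
    if missing:
        raise ValueError(
            f"found {len(found)} of {len(markers)} alignment markers; "
            f"missing marker indices: {missing}")
    return np.asarray(found)


def estimate_pose(centroids: np.ndarray, geometry: PhantomGeometry
                  ) -> PoseEstimate:
    """Least-squares rigid registration of marker centroids to the geometry.

    Requires at least three non-collinear markers.  Angles are extracted
    in the intrinsic z-y-x (yaw, pitch, roll) convention, degrees.
    """
    P = np.asarray([m.center for m in geometry.alignment_markers], dtype=float)
    Q = np.asarray(centroids, dtype=float)
    if Q.shape != P.shape:
        raise ValueError(f"expected {P.shape[0]} centroids, got {Q.shape[0]}")
    if P.shape[0] < 3:
        raise ValueError("pose estimation needs at least 3 markers")
    Pc = P - P.mean(axis=0)
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise ValueError("marker positions are collinear; pose is degenerate")

    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T  # maps centred geometry points onto centred centroids

    yaw, pitch, roll = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    c = geometry.center
    t_full = Q.mean(axis=0) - (R @ (P.mean(axis=0) - c) + c)
    resid = np.sqrt(np.mean(np.sum((Qc - Pc @ R.T) ** 2, axis=1)))
    return PoseEstimate(roll=float(roll), pitch=float(pitch), yaw=float(yaw),
                        translation=(float(t_full[0]), float(t_full[1])),
                        residual_mm=float(resid), center=tuple(c))
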