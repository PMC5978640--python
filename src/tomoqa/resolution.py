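"""In-plane PSF extraction and MTF computation.

The 0.18 mm ramp beads act as point sources at current tomosynthesis
resolution (pixel pitch ~0.1 mm); a background-subtracted patch around a
bead on its in-focus slice is the sampled point spread function, and the
normalised modulus of its Fourier transform along the frequency axes
gives MTF(x) and MTF(y).  The MTF concept is not strictly valid for
nonlinear, non-isoplanatic reconstructions; what is computed here is the
FT-of-PSF MTF, labelled as such in report provenance.

Tube travel typically blurs the x direction more than y, so MTF(x) lies
below MTF(y); anisotropic PSFs can push modulation above the zero-
frequency value, and such values are reported as-is, never clipped.

As resolution improves the bead's own size can be deconvolved: the bead's
in-plane object function is the z-projection of a uniform ball, whose
transform 3(sin u - u cos u)/u^3 (u = 2 pi f r) divides the measured
curve, with a regularisation floor on the divisor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import center_of_mass, shift as nd_shift

from .positioning import PoseEstimate, identity_pose
from .volume import ReconVolume

__all__ = ["PSFPatch", "MTFCurve", "extract_psf", "mtf_from_psf",
           "average_mtf"]


@dataclass
class PSFPatch:
    """Background-subtracted 2D PSF sample centred on a bead."""

    data: np.ndarray  # (ny, nx), background subtracted
    pixel_spacing: float  # mm
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("PSF patch must be 2D")
        if self.data.sum() <= 0:
            raise ValueError("PSF patch must have positive total signal")
        cy, cx = center_of_mass(np.clip(self.data, 0, None))
        my, mx = (self.data.shape[0] - 1) / 2.0, (self.data.shape[1] - 1) / 2.0
        if abs(cy - my) > 1.0 or abs(cx - mx) > 1.0:
            raise ValueError("PSF centroid more than 1 pixel from centre")

    def second_moment(self, axis: str) -> float:
        """RMS width (mm) of the patch along x or y."""
        w = np.clip(self.data, 0, None)
        cy, cx = center_of_mass(w)
        ny, nx = self.data.shape
        if axis == "x":
            coords = (np.arange(nx) - cx) * self.pixel_spacing
            marg = w.sum(axis=0)
        else:
            coords = (np.arange(ny) - cy) * self.pixel_spacing
            marg = w.sum(axis=1)
        return float(np.sqrt((marg * coords ** 2).sum() / marg.sum()))


@dataclass
class MTFCurve:
    frequency: np.ndarray  # cycles/mm, >= 0 up to Nyquist
    modulation: np.ndarray  # normalised to 1 at DC; values > 1 not clipped
    axis: str  # "x" | "y"
    deconvolved: bool = False
    truncated: bool = False
    modulation_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.modulation = np.asarray(self.modulation, dtype=float)
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")

    def at(self, f: float) -> float:
        return float(np.interp(f, self.frequency, self.modulation))

    @property
    def nyquist(self) -> float:
        return float(self.frequency[-1])


def extract_psf(vol: ReconVolume, bead_position, pose: PoseEstimate | None
                = None, patch_size_mm: float = 1.5,
                contamination_fraction: float = 0.2) -> PSFPatch:
    """Extract the in-plane PSF patch around a bead on its in-focus slice.

    The patch-border median is subtracted as background and the patch is
    recentred to sub-pixel precision by centroid shift.  A secondary peak
    above ``contamination_fraction`` of the main peak (outside the main
    lobe) indicates a neighbouring bead inside the patch and is an error.
    """
    if pose is None:
        pose = identity_pose()
    c = pose.to_image(np.asarray(bead_position, dtype=float))
    dz, dy, dx = vol.spacing
    k = vol.slice_nearest(c[2])
    half = int(round(patch_size_mm / 2.0 / dx))
    if half < 3:
        raise ValueError("patch size too small")
    _, iy, ix = vol.world_to_index(c)
    iy0, ix0 = int(round(iy)), int(round(ix))
    ny, nx = vol.shape[1:]
    if (iy0 - half - 1 < 0 or iy0 + half + 2 > ny
            or ix0 - half - 1 < 0 or ix0 + half + 2 > nx):
        raise ValueError("PSF patch extends outside the imaged field")
    patch = vol.intensities[k, iy0 - half:iy0 + half + 1,
                            ix0 - half:ix0 + half + 1].astype(np.float64)
    border = np.concatenate([patch[0], patch[-1], patch[1:-1, 0],
                             patch[1:-1, -1]])
    patch = patch - np.median(border)

    peak = patch.max()
    if peak <= 0:
        raise ValueError("no signal above background in PSF patch")
    # contamination check: more than one distinct lobe (connected region
    # or separated local maximum) above the threshold means a
    # neighbouring bead sits inside the patch
    from scipy.ndimage import label, maximum_filter
    mask = patch > contamination_fraction * peak
    n_regions = label(mask)[1]
    locmax = (patch == maximum_filter(patch, size=3)) & mask
    n_peaks = label(locmax)[1]
    if n_regions > 1 or n_peaks > 1:
        raise ValueError("secondary peak in PSF patch: neighbouring bead "
                         "contaminates the point source")

    w = np.clip(patch, 0, None)
    cy, cx = center_of_mass(w)
    my, mx = (patch.shape[0] - 1) / 2.0, (patch.shape[1] - 1) / 2.0
    patch = nd_shift(patch, (my - cy, mx - cx), order=3, mode="nearest")
    return PSFPatch(patch, pixel_spacing=dx,
                    source=f"bead@{tuple(np.round(c, 2))}/slice{k}")


def _ball_projection_mtf(f: np.ndarray, diameter_mm: float) -> np.ndarray:
    """Normalised transform of the z-projection of a uniform ball."""
    r = diameter_mm / 2.0
    u = 2.0 * np.pi * np.asarray(f, dtype=float) * r
    out = np.ones_like(u)
    nz = np.abs(u) > 1e-9
    out[nz] = 3.0 * (np.sin(u[nz]) - u[nz] * np.cos(u[nz])) / u[nz] ** 3
    return out


def mtf_from_psf(patch: PSFPatch, deconvolve_bead: bool = False,
                 bead_diameter_mm: float = 0.18,
                 window: str | None = "hann", pad_factor: int = 4,
                 eps: float = 0.05) -> tuple[MTFCurve, MTFCurve]:
    """MTF(x) and MTF(y) from a PSF patch by discrete Fourier transform.

    The patch is multiplied by a Hann window (suppresses truncation
    ripple; ``window=None`` disables), zero-padded to ``pad_factor`` times
    its size for frequency resolution, transformed, and the modulus along
    the frequency axes through DC is normalised to 1 at DC.  With
    ``deconvolve_bead`` the curves are divided by the bead's projected-
    ball transform; where that divisor falls below ``eps`` the curve is
    truncated and flagged.
    """
    data = patch.data
    ny, nx = data.shape
    if window == "hann":
        wy = np.hanning(ny)
        wx = np.hanning(nx)
        data = data * np.outer(wy, wx)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    n = int(pad_factor * max(ny, nx))
    F = np.fft.fft2(data, s=(n, n))
    mod = np.abs(F)
    dc = mod[0, 0]
    if dc <= 0:
        raise ValueError("zero DC component; cannot normalise MTF")
    freqs = np.fft.fftfreq(n, d=patch.pixel_spacing)
    keep = n // 2 + 1  # f >= 0 up to Nyquist
    f = freqs[:keep].copy()
    f[-1] = abs(f[-1])
    curve_x = mod[0, :keep] / dc
    curve_y = mod[:keep, 0] / dc

    truncated = False
    if deconvolve_bead:
        div = _ball_projection_mtf(f, bead_diameter_mm)
        ok = div >= eps
        if not np.all(ok):
            truncated = True
            last = int(np.argmin(ok))
            f = f[:last]
            curve_x = curve_x[:last]
            curve_y = curve_y[:last]
            div = div[:last]
        curve_x = curve_x / div
        curve_y = curve_y / div

    return (MTFCurve(f, curve_x, "x", deconvolved=deconvolve_bead,
                     truncated=truncated),
            MTFCurve(f, curve_y, "y", deconvolved=deconvolve_bead,
                     truncated=truncated))


def average_mtf(curves: list[MTFCurve]) -> MTFCurve:
    """Pointwise mean of replicate MTF curves with per-frequency SD."""
    if not curves:
        raise ValueError("need at least one curve")
    axis = curves[0].axis
    f = curves[0].frequency
    for c in curves[1:]:
        if c.axis != axis:
            raise ValueError("cannot average MTF curves of mixed axes")
        if len(c.frequency) != len(f) or not np.allclose(c.frequency, f):
            raise ValueError("curves must share a frequency grid")
    stack = np.vstack([c.modulation for c in curves])
    return MTFCurve(f, stack.mean(axis=0), axis,
                    deconvolved=curves[0].deconvolved,
                    modulation_sd=stack.std(axis=0, ddof=0))
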