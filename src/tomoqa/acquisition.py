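"""Acquisition model: slice profile, in-plane blur, noise-vs-mAs and pose.

The slice profile is the through-plane response a reconstructed slice
applies to the object function; its full width at half maximum is the
nominal slice width.  Profiles are normalised to unit area so that a thick
uniform object reproduces its full contrast while a point-like object
traces the profile shape across slices.

Noise is zero-mean Gaussian with a standard deviation that scales as a
power of the tube loading, SD = base_sd * (mAs / ref_mAs)**exponent; the
default exponent of -0.5 models the approximate square-root dependence of
reconstructed noise on mAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.spatial.transform import Rotation

__all__ = ["AcquisitionModel", "SliceProfile"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class SliceProfile:
    """Unit-area through-plane profile of a given shape and FWHM (mm)."""

    SHAPES = ("gaussian", "triangular", "rectangular")

    def __init__(self, shape: str, fwhm: float):
        if shape not in self.SHAPES:
            raise ValueError(f"unknown slice profile shape {shape!r}")
        if fwhm <= 0:
            raise ValueError("slice profile FWHM must be positive")
        self.shape = shape
        self.fwhm = float(fwhm)

    @property
    def support(self) -> float:
        """Half-width beyond which the profile is (numerically) zero."""
        if self.shape == "gaussian":
            return 4.5 * self.fwhm * _FWHM_TO_SIGMA
        if self.shape == "triangular":
            return self.fwhm  # triangle of base 2*fwhm has FWHM = fwhm
        return self.fwhm / 2.0

    def __call__(self, z) -> np.ndarray:
        """Profile value at offset z (mm); peak = 1/area-normalisation."""
        z = np.asarray(z, dtype=float)
        if self.shape == "gaussian":
            s = self.fwhm * _FWHM_TO_SIGMA
            return np.exp(-0.5 * (z / s) ** 2) / (s * np.sqrt(2 * np.pi))
        if self.shape == "triangular":
            a = self.fwhm
            return np.clip(1.0 - np.abs(z) / a, 0.0, None) / a
        w = self.fwhm
        return np.where(np.abs(z) <= w / 2.0, 1.0 / w, 0.0)

    def cdf(self, z) -> np.ndarray:
        """Integral of the unit-area profile from -inf to z."""
        z = np.asarray(z, dtype=float)
        if self.shape == "gaussian":
            s = self.fwhm * _FWHM_TO_SIGMA
            return ndtr(z / s)
        if self.shape == "triangular":
            a = self.fwhm
            u = np.clip(z / a, -1.0, 1.0)
            return np.where(u < 0, 0.5 * (1 + u) ** 2, 1 - 0.5 * (1 - u) ** 2)
        w = self.fwhm
        return np.clip(z / w + 0.5, 0.0, 1.0)

    def interval_integral(self, za, zb, z_slice) -> np.ndarray:
        """Integral of the profile centred on ``z_slice`` over [za, zb]."""
        return self.cdf(np.asarray(zb) - z_slice) - self.cdf(
            np.asarray(za) - z_slice)


@dataclass(frozen=True)
class AcquisitionModel:
    """Parameters of the simulated acquisition / reconstruction."""

    pixel_spacing_xy: float = 0.1  # mm, isotropic in-plane
    slice_increment: float = 1.0  # mm between slice centres
    nominal_slice_width: float = 1.0  # slice profile FWHM, mm
    slice_profile: str = "gaussian"  # gaussian | triangular | rectangular
    inplane_blur: tuple[float, float] = (0.18, 0.12)  # (sigma_x, sigma_y) mm
    noise_base_sd: float = 8.0  # SD at the reference mAs
    noise_ref_mas: float = 50.0
    noise_exponent: float = -0.5
    mas: float = 50.0
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0)  # roll, pitch, yaw deg
    translation_xy: tuple[float, float] = (0.0, 0.0)  # mm
    background_level: float = 1000.0
    chest_wall_offset: float = 0.0  # mm of field lost at the chest wall
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_spacing_xy <= 0 or self.slice_increment <= 0:
            raise ValueError("spacings must be positive")
        if self.nominal_slice_width <= 0:
            raise ValueError("nominal_slice_width must be positive")
        if self.noise_base_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.mas <= 0 or self.noise_ref_mas <= 0:
            raise ValueError("mAs values must be positive")
        SliceProfile(self.slice_profile, self.nominal_slice_width)

    def profile(self) -> SliceProfile:
        return SliceProfile(self.slice_profile, self.nominal_slice_width)

    def noise_sd(self, mas: float | None = None) -> float:
        """Noise SD at the given (default: configured) mAs."""
        m = self.mas if mas is None else mas
        return self.noise_base_sd * (m / self.noise_ref_mas) ** self.noise_exponent

    def rotation(self) -> Rotation:
        """Rigid pose rotation, intrinsic z-y-x (yaw, pitch, roll), degrees."""
        roll, pitch, yaw = self.pose
        return Rotation.from_euler("ZYX", [yaw, pitch, roll], degrees=True)
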