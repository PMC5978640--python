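"""SSP extraction, FWHM, slice incrementation, z-bead spacing, ASF."""

import dataclasses

import numpy as np
import pytest

from tomoqa.acquisition import AcquisitionModel
from tomoqa.geometry import PhantomGeometry, Sphere
from tomoqa.positioning import estimate_pose, locate_markers
from tomoqa.simulate import render
from tomoqa.slice_geometry import (SSPCurve, asf, extract_ssp, fwhm,
                                   slice_incrementation, slice_width,
                                   z_bead_spacing)


def synthetic_curve(profile, width, z0=21.0, span=6.0):
    z = np.arange(z0 - span, z0 + span + 1e-9, 0.05)
    if profile == "rect":
        v = (np.abs(z - z0) <= width / 2).astype(float)
    else:
        sigma = width / 2.3548200450309493
        v = np.exp(-0.5 * ((z - z0) / sigma) ** 2)
    return SSPCurve(z=z, sensitivity=v, source="synthetic")


class TestFWHM:
    def test_rect_three_mm(self):
        assert fwhm(synthetic_curve("rect", 3.0)) == pytest.approx(3.0,
                                                                   abs=0.05)

    def test_gaussian_sigma_one(self):
        c = synthetic_curve("gauss", 2.3548200450309493)  # sigma = 1 mm
        assert fwhm(c) == pytest.approx(2.3548, abs=0.01)

    def test_truncated_profile_is_error(self):
        c = synthetic_curve("gauss", 8.0, span=2.0)  # never falls below half
        with pytest.raises(ValueError, match="crossing"):
            fwhm(c)


class TestExtractSSP:
    def test_rectangular_profile_recovered(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(slice_profile="rectangular",
                                nominal_slice_width=3.0, noise_base_sd=0.0)
        k = v.slice_nearest(21.0)
        c = extract_ssp(v, ramp, k)
        assert fwhm(c) == pytest.approx(3.0, abs=0.15)
        # rectangular SSP: flat top near 1 around the slice centre
        inside = np.abs(c.z - v.z_positions[k]) < 1.0
        assert c.sensitivity[inside].min() > 0.9

    def test_gaussian_peak_at_slice_center(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(noise_base_sd=0.0)
        k = v.slice_nearest(21.0)
        c = extract_ssp(v, ramp, k)
        assert c.peak_z == pytest.approx(v.z_positions[k], abs=0.25)

    def test_normalised_peak_is_one(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(seed=3)
        c = extract_ssp(v, ramp, v.slice_nearest(21.0))
        assert c.sensitivity.max() == pytest.approx(1.0)
        assert np.all(np.diff(c.z) > 0)

    def test_left_right_ramps_agree(self, geom, default_volume):
        k = default_volume.slice_nearest(21.0)
        f = [fwhm(extract_ssp(default_volume, r, k)) for r in geom.ramps]
        assert abs(f[0] - f[1]) <= 0.1 * max(f)

    def test_limbs_agree_within_ten_percent(self, ramp, ramp_volume_factory):
        from tomoqa.geometry import bead_positions
        v = ramp_volume_factory(seed=5)
        k = v.slice_nearest(21.0)
        n1 = ramp.n_beads_lower
        lower = dataclasses.replace(ramp, total_rise=5.0)  # lower limb span
        c = extract_ssp(v, ramp, k)
        # split the merged curve at the fold and measure each limb
        zs, vs = c.raw_z, c.raw_sensitivity
        fold_z = bead_positions(ramp)[n1 - 1, 2]
        widths = []
        for sel in (zs <= fold_z, zs > fold_z):
            if vs[sel].max() < 0.9:  # limb missing the peak: skip
                continue
            sub = SSPCurve(z=np.arange(zs[sel][0], zs[sel][-1], 0.05),
                           sensitivity=np.interp(
                               np.arange(zs[sel][0], zs[sel][-1], 0.05),
                               zs[sel], vs[sel] / vs[sel].max()),
                           source="limb")
            try:
                widths.append(fwhm(sub))
            except ValueError:
                pass
        if len(widths) == 2:
            assert abs(widths[0] - widths[1]) <= 0.1 * max(widths)

    def test_too_few_peaks_is_error(self, ramp, ramp_geom):
        # a 6 mm slice far from the ramp span leaves no resolvable peaks
        v = render(ramp_geom, AcquisitionModel(seed=2))
        with pytest.raises(ValueError, match="resolvable"):
            extract_ssp(v, ramp, 2)  # slice z=2.5, ramp spans 16-26


class TestSliceWidthAccuracy:
    @pytest.mark.parametrize("width", [1.0, 3.0])
    def test_within_half_mm_of_nominal(self, ramp, ramp_volume_factory,
                                       width):
        v = ramp_volume_factory(nominal_slice_width=width, seed=8)
        assert slice_width(v, ramp) == pytest.approx(width, abs=0.5)


class TestSliceIncrementation:
    def test_one_mm_increment(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(seed=4)
        res = slice_incrementation(v, ramp)
        assert res.mean_mm == pytest.approx(1.0, abs=0.1)
        assert not res.outliers.any()

    def test_half_mm_increment(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(slice_increment=0.5, seed=4)
        res = slice_incrementation(v, ramp)
        assert res.mean_mm == pytest.approx(0.5, abs=0.1)

    def test_duplicate_slice_flagged(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(seed=4)
        dup = dataclasses.replace(v)
        k = v.slice_nearest(21.0)
        arr = v.intensities.copy()
        arr[k + 1] = arr[k]  # duplicated slice: zero effective increment
        dup.intensities = arr
        res = slice_incrementation(dup, ramp)
        assert res.outliers.any()

    def test_too_few_slices_rejected(self, ramp, ramp_volume_factory):
        v = ramp_volume_factory(seed=4)
        with pytest.raises(ValueError):
            slice_incrementation(v, ramp, slice_indices=[20, 21])


class TestZBeadSpacing:
    def test_default_spacing_ten_mm(self, geom, default_volume):
        spac = z_bead_spacing(default_volume, geom)
        assert len(spac) == 2
        np.testing.assert_allclose(spac, 10.0, atol=0.3)

    def test_eight_mm_spacing(self):
        zc = 21.0
        g = PhantomGeometry(
            x_range=(-8, 8), y_range=(56, 72),
            z_beads=tuple(Sphere(center=(0.0, 64.0, z), diameter=5.0,
                                 contrast=3.0)
                          for z in (zc - 8, zc, zc + 8)))
        v = render(g, AcquisitionModel(seed=3))
        np.testing.assert_allclose(z_bead_spacing(v, g), 8.0, atol=0.3)

    def test_identical_z_gives_zero_spacing(self):
        g = PhantomGeometry(
            x_range=(-12, 12), y_range=(56, 72),
            z_beads=(Sphere(center=(-5.0, 64.0, 21.0), diameter=5.0,
                            contrast=3.0),
                     Sphere(center=(5.0, 64.0, 21.0), diameter=5.0,
                            contrast=3.0)))
        v = render(g, AcquisitionModel(seed=3))
        np.testing.assert_allclose(z_bead_spacing(v, g), 0.0, atol=0.15)

    def test_missing_bead_is_error(self, geom):
        stripped = dataclasses.replace(geom, z_beads=geom.z_beads[:1]
                                       + geom.z_beads[2:])
        v = render(stripped, AcquisitionModel(seed=3))
        with pytest.raises(ValueError, match="bead"):
            z_bead_spacing(v, geom)

    def test_invariant_under_inplane_translation(self, geom):
        acq = AcquisitionModel(seed=6, translation_xy=(1.5, -1.0))
        v = render(geom, acq)
        pose = estimate_pose(locate_markers(v, geom), geom)
        np.testing.assert_allclose(z_bead_spacing(v, geom, pose), 10.0,
                                   atol=0.3)


class TestASF:
    def small_bead_geom(self):
        return PhantomGeometry(
            x_range=(-8, 8), y_range=(0, 16),
            z_beads=(Sphere(center=(0.0, 8.0, 21.0), diameter=0.3,
                            contrast=25.0),))

    def test_isotropic_blur_gives_matching_axes(self):
        g = self.small_bead_geom()
        v = render(g, AcquisitionModel(noise_base_sd=0.0,
                                       inplane_blur=(0.2, 0.2)))
        ax, ay = asf(v, g.z_beads[0].center)
        np.testing.assert_allclose(ax.response, ay.response, atol=0.02)

    def test_anisotropic_blur_widens_x(self):
        g = self.small_bead_geom()
        v = render(g, AcquisitionModel(noise_base_sd=0.0,
                                       inplane_blur=(0.5, 0.15)))
        ax, ay = asf(v, g.z_beads[0].center)
        assert ax.width_at_half_max() > ay.width_at_half_max()
        # analytic oracle: gaussian-dominated widths ~ 2.355 sigma
        assert ax.width_at_half_max() == pytest.approx(2.3548 * 0.5,
                                                       rel=0.15)

    def test_peak_at_zero_offset(self, geom, default_volume):
        ax, ay = asf(default_volume, geom.z_beads[1].center)
        assert abs(ax.offset[np.argmax(ax.response)]) <= 0.5
        assert abs(ay.offset[np.argmax(ay.response)]) <= 0.5

    def test_symmetric_domain(self, geom, default_volume):
        ax, _ = asf(default_volume, geom.z_beads[1].center)
        np.testing.assert_allclose(ax.offset, -ax.offset[::-1])
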