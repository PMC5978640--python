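"""PSF extraction and FT-of-PSF MTF."""

import numpy as np
import pytest

from tomoqa.acquisition import AcquisitionModel
from tomoqa.geometry import PhantomGeometry, Sphere, bead_positions
from tomoqa.resolution import (MTFCurve, PSFPatch, average_mtf, extract_psf,
                               mtf_from_psf)
from tomoqa.simulate import render


def gaussian_patch(sigma_mm=0.2, dx=0.1, n=65, sigma_y=None):
    c = (n - 1) / 2.0
    xs = (np.arange(n) - c) * dx
    sy = sigma_y or sigma_mm
    return PSFPatch(np.exp(-(xs[None, :] ** 2 / sigma_mm ** 2
                             + xs[:, None] ** 2 / sy ** 2) / 2.0), dx)


class TestMTFFromPSF:
    def test_delta_psf_gives_unit_mtf(self):
        d = np.zeros((33, 33))
        d[16, 16] = 1.0
        mx, my = mtf_from_psf(PSFPatch(d, 0.1), window=None)
        np.testing.assert_allclose(mx.modulation, 1.0, atol=1e-12)
        np.testing.assert_allclose(my.modulation, 1.0, atol=1e-12)

    def test_gaussian_closed_form(self):
        sigma = 0.2
        mx, my = mtf_from_psf(gaussian_patch(sigma))
        ref = np.exp(-2 * np.pi ** 2 * sigma ** 2 * mx.frequency ** 2)
        half_nyq = mx.frequency <= 2.5
        assert np.abs(mx.modulation - ref)[half_nyq].max() < 0.03
        # MTF = 0.5 near 0.94 cycles/mm for sigma = 0.2 mm
        f50 = np.interp(0.5, mx.modulation[::-1], mx.frequency[::-1])
        assert f50 == pytest.approx(0.9394, abs=0.03)

    def test_dc_normalisation_and_nyquist(self):
        mx, _ = mtf_from_psf(gaussian_patch())
        assert mx.modulation[0] == pytest.approx(1.0)
        assert mx.nyquist == pytest.approx(5.0)  # 1/(2 * 0.1 mm)
        assert np.all(mx.frequency >= 0)

    def test_anisotropic_blur_orders_axes(self):
        mx, my = mtf_from_psf(gaussian_patch(0.35, sigma_y=0.15))
        sel = (mx.frequency > 0) & (my.modulation > 0.02)
        assert np.all(mx.modulation[sel] < my.modulation[sel])

    def test_values_above_one_not_clipped(self):
        # two-point PSF produces modulation lobes; synthetic curve check
        # that the pipeline reports super-DC values verbatim
        c = MTFCurve(np.array([0.0, 1.0]), np.array([1.0, 1.1]), "x")
        assert c.at(1.0) == pytest.approx(1.1)
        d = np.zeros((33, 33))
        d[16, 14] = d[16, 18] = 1.0
        d[16, 16] = -0.5  # undershoot as from edge-enhancing filters
        mx, _ = mtf_from_psf(PSFPatch(d, 0.1), window=None)
        assert mx.modulation.max() > 1.0  # interference lobes kept as-is

    def test_parseval_energy_conserved(self):
        p = gaussian_patch()
        n = p.data.shape[0]
        F = np.fft.fft2(p.data)
        assert np.sum(np.abs(F) ** 2) / n ** 2 == pytest.approx(
            np.sum(p.data ** 2), rel=1e-10)

    def test_deconvolution_identity_for_point_bead(self):
        mx, _ = mtf_from_psf(gaussian_patch())
        dx, _ = mtf_from_psf(gaussian_patch(), deconvolve_bead=True,
                             bead_diameter_mm=0.02)
        half_nyq = mx.frequency <= 2.5
        rel = np.abs(dx.modulation[half_nyq] - mx.modulation[half_nyq]) \
            / np.maximum(mx.modulation[half_nyq], 1e-12)
        assert rel.max() < 0.01

    def test_deconvolution_truncates_and_flags(self):
        # a large bead's transform crosses the regularisation floor
        dx, dy = mtf_from_psf(gaussian_patch(), deconvolve_bead=True,
                              bead_diameter_mm=2.0, eps=0.05)
        assert dx.truncated and dy.truncated
        assert dx.nyquist < 5.0


class TestExtractPSF:
    def bead_volume(self, blur=(0.2, 0.2)):
        g = PhantomGeometry(
            x_range=(-6, 6), y_range=(0, 12),
            z_beads=(Sphere(center=(0.0, 6.0, 21.0), diameter=0.18,
                            contrast=25.0),))
        return g, render(g, AcquisitionModel(noise_base_sd=0.0,
                                             inplane_blur=blur))

    def test_second_moment_matches_blur(self):
        g, v = self.bead_volume()
        patch = extract_psf(v, g.z_beads[0].center)
        assert patch.second_moment("x") == pytest.approx(0.2, abs=0.03)
        assert patch.second_moment("y") == pytest.approx(0.2, abs=0.03)

    def test_sharp_bead_is_compact(self):
        g, v = self.bead_volume(blur=(0.05, 0.05))
        patch = extract_psf(v, g.z_beads[0].center)
        peak = patch.data.max()
        # nearly all energy within a 3x3 neighbourhood of the peak
        py, px = np.unravel_index(np.argmax(patch.data), patch.data.shape)
        core = patch.data[py - 1:py + 2, px - 1:px + 2].sum()
        assert core / patch.data.sum() > 0.9
        assert peak > 0

    def test_neighbour_contamination_rejected(self):
        g = PhantomGeometry(
            x_range=(-6, 6), y_range=(0, 12),
            z_beads=(Sphere(center=(0.0, 6.0, 21.0), diameter=0.18,
                            contrast=25.0),
                     Sphere(center=(0.3, 6.0, 21.0), diameter=0.18,
                            contrast=25.0)))
        v = render(g, AcquisitionModel(noise_base_sd=0.0,
                                       inplane_blur=(0.08, 0.08)))
        with pytest.raises(ValueError, match="secondary peak"):
            extract_psf(v, g.z_beads[0].center)

    def test_ramp_bead_psf_from_default_volume(self, geom, default_volume):
        pts = bead_positions(geom.ramps[0])
        zs = default_volume.z_positions
        in_focus = (np.abs(pts[:, 2][:, None] - zs[None, :]).min(axis=1)
                    <= 0.25)
        away_from_fold = np.abs(pts[:, 2] - 21.0) > 1.0
        bead = pts[in_focus & away_from_fold][0]
        patch = extract_psf(default_volume, bead)
        assert patch.data.sum() > 0

    def test_patch_outside_field_rejected(self):
        g, v = self.bead_volume()
        with pytest.raises(ValueError, match="outside"):
            extract_psf(v, (5.9, 6.0, 21.0))


class TestAverageMTF:
    def curves(self, n, rng=None):
        f = np.linspace(0, 5, 21)
        out = []
        for i in range(n):
            mod = np.exp(-0.3 * f)
            if rng is not None:
                mod = mod + rng.normal(0, 0.02, f.shape)
            out.append(MTFCurve(f, mod, "x"))
        return out

    def test_identical_curves_average_to_same(self):
        avg = average_mtf(self.curves(3))
        np.testing.assert_allclose(avg.modulation,
                                   np.exp(-0.3 * avg.frequency))
        np.testing.assert_allclose(avg.modulation_sd, 0.0, atol=1e-15)

    def test_two_curves_mean_halfway(self):
        f = np.array([0.0, 1.0])
        c1 = MTFCurve(f, np.array([1.0, 0.2]), "x")
        c2 = MTFCurve(f, np.array([1.0, 0.6]), "x")
        avg = average_mtf([c1, c2])
        assert avg.modulation[1] == pytest.approx(0.4)

    def test_replicate_sd_shrinks_with_averaging(self, rng):
        # SD across means of 10-replicate groups ~ single-curve SD / sqrt(10)
        singles = np.array([c.modulation[10] for c in self.curves(400, rng)])
        groups = singles.reshape(40, 10).mean(axis=1)
        ratio = singles.std() / groups.std()
        assert ratio == pytest.approx(np.sqrt(10), rel=0.35)

    def test_mixed_axes_rejected(self):
        f = np.linspace(0, 5, 10)
        with pytest.raises(ValueError, match="axes"):
            average_mtf([MTFCurve(f, f * 0 + 1, "x"),
                         MTFCurve(f, f * 0 + 1, "y")])
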