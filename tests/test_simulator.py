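"""Renderer: analytic solids, slice profile, noise model, pose, truth."""

import dataclasses

import numpy as np
import pytest

from tomoqa.acquisition import AcquisitionModel, SliceProfile
from tomoqa.geometry import PhantomGeometry, Sphere
from tomoqa.simulate import render, render_series, truth_record


def sphere_geom(center=(0.0, 8.0, 21.0), diameter=0.18, contrast=25.0,
                **kwargs):
    kwargs.setdefault("x_range", (-5.0, 5.0))
    kwargs.setdefault("y_range", (0.0, 16.0))
    return PhantomGeometry(
        low_contrast_spheres=(Sphere(center=center, diameter=diameter,
                                     contrast=contrast),), **kwargs)


class TestSliceProfile:
    @pytest.mark.parametrize("shape", SliceProfile.SHAPES)
    def test_unit_area_and_fwhm(self, shape):
        for w in (0.5, 1.0, 3.0):
            p = SliceProfile(shape, w)
            z = np.linspace(-5 * w, 5 * w, 20001)
            area = np.trapezoid(p(z), z)
            assert area == pytest.approx(1.0, rel=1e-3)
            # FWHM of the analytic profile equals the nominal width
            v = p(z)
            above = z[v >= 0.5 * v.max()]
            assert above[-1] - above[0] == pytest.approx(w, abs=2e-3)

    @pytest.mark.parametrize("shape", SliceProfile.SHAPES)
    def test_cdf_matches_numeric_integral(self, shape):
        p = SliceProfile(shape, 2.0)
        z = np.linspace(-4, 4, 2001)
        numeric = np.cumsum(p(z)) * (z[1] - z[0])
        assert np.allclose(p.cdf(z), numeric, atol=5e-3)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            SliceProfile("boxcar", 1.0)


class TestRender:
    def test_empty_geometry_zero_noise_is_constant(self):
        g = PhantomGeometry(x_range=(-3, 3), y_range=(0, 6))
        v = render(g, AcquisitionModel(noise_base_sd=0.0))
        assert np.all(v.intensities == 1000.0)

    @pytest.mark.parametrize("shape", SliceProfile.SHAPES)
    def test_bead_peak_on_nearest_slice(self, shape):
        z0 = 23.2
        g = sphere_geom(center=(0.0, 8.0, z0))
        v = render(g, AcquisitionModel(noise_base_sd=0.0,
                                       slice_profile=shape))
        per_slice_max = v.intensities.max(axis=(1, 2))
        k = int(np.argmax(per_slice_max))
        assert k == v.slice_nearest(z0)

    def test_bead_z_profile_matches_analytic_convolution(self):
        # point-like bead: the through-slice response IS the profile
        z0 = 21.0
        g = sphere_geom(center=(0.0, 8.0, z0))
        acq = AcquisitionModel(noise_base_sd=0.0, nominal_slice_width=3.0)
        v = render(g, acq)
        prof = acq.profile()
        resp = v.intensities.max(axis=(1, 2)) - 1000.0
        expected = prof(v.z_positions - z0)
        np.testing.assert_allclose(resp / resp.max(),
                                   expected / expected.max(), atol=0.02)

    def test_noise_sd_scales_as_inverse_sqrt_mas(self):
        g = PhantomGeometry(x_range=(-6, 6), y_range=(0, 12))
        sd = {}
        for mas in (50.0, 200.0):
            acq = AcquisitionModel(mas=mas, seed=9)
            v = render(g, acq)
            sd[mas] = v.intensities[10:20].std()
        assert sd[50.0] / sd[200.0] == pytest.approx(2.0, rel=0.10)

    def test_contrast_linearity(self):
        base = sphere_geom(diameter=4.0, contrast=0.02)
        doubled = sphere_geom(diameter=4.0, contrast=0.04)
        acq = AcquisitionModel(noise_base_sd=0.0)
        net1 = render(base, acq).intensities - 1000.0
        net2 = render(doubled, acq).intensities - 1000.0
        assert np.abs(net2 - 2 * net1).max() < 1e-3 * net1.max()

    def test_identity_pose_keeps_centroids(self, geom, noiseless_volume):
        tr = truth_record(geom, AcquisitionModel(noise_base_sd=0.0))
        v = noiseless_volume
        for m, truth in zip(geom.alignment_markers, tr["markers_xyz_mm"]):
            assert np.allclose(m.center, truth)
            iz, iy, ix = v.world_to_index(np.asarray(truth))
            k = int(round(iz))
            patch = v.intensities[k, int(iy) - 20:int(iy) + 21,
                                  int(ix) - 20:int(ix) + 21]
            py, px = np.unravel_index(np.argmax(patch), patch.shape)
            # centroid of the rendered marker within one voxel of truth
            assert abs(py - 20 - (iy - int(iy))) <= 1
            assert abs(px - 20 - (ix - int(ix))) <= 1

    def test_seed_determinism(self):
        g = sphere_geom()
        acq = AcquisitionModel(seed=4)
        v1 = render(g, acq)
        v2 = render(g, acq)
        assert np.array_equal(v1.intensities, v2.intensities)
        v3 = render(g, dataclasses.replace(acq, seed=5))
        assert not np.array_equal(v1.intensities, v3.intensities)

    def test_truth_record_tracks_pose(self):
        # sphere away from the rotation centre so yaw must move it
        g = sphere_geom(center=(3.0, 2.0, 21.0))
        acq = AcquisitionModel(pose=(0.0, 0.0, 5.0), noise_base_sd=0.0)
        tr = truth_record(g, acq)
        c = np.asarray(tr["spheres"][0]["center_xyz_mm"])
        assert not np.allclose(c[:2], (3.0, 2.0))  # yaw moves it in-plane
        assert c[2] == pytest.approx(21.0)  # yaw preserves z


class TestRenderSeries:
    def test_single_mas_gives_one_volume(self):
        g = PhantomGeometry(x_range=(-3, 3), y_range=(0, 6))
        assert len(render_series(g, AcquisitionModel(), [50.0])) == 1

    def test_noise_free_series_identical(self):
        g = PhantomGeometry(x_range=(-3, 3), y_range=(0, 6))
        acq = AcquisitionModel(noise_base_sd=0.0)
        vols = render_series(g, acq, [25.0, 50.0, 100.0])
        assert len(vols) == 3
        for v in vols[1:]:
            assert np.array_equal(v.intensities, vols[0].intensities)

    def test_measured_sd_ratio_two_for_4x_mas(self):
        g = PhantomGeometry(x_range=(-6, 6), y_range=(0, 12))
        vols = render_series(g, AcquisitionModel(seed=2), [25.0, 100.0])
        r = vols[0].intensities.std() / vols[1].intensities.std()
        assert r == pytest.approx(2.0, rel=0.10)

    def test_rejects_bad_mas_list(self):
        g = PhantomGeometry(x_range=(-3, 3), y_range=(0, 6))
        with pytest.raises(ValueError):
            render_series(g, AcquisitionModel(), [])
        with pytest.raises(ValueError):
            render_series(g, AcquisitionModel(), [50.0, -1.0])
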