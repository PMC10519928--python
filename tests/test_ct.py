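"""Phantom calibration, segmentation, CSA/TV/BMD profiles, normalization."""

import numpy as np
import pytest

import callusmon as cm
from callusmon import ct
from callusmon.ct import CalibrationError, VoxelVolume


def block_volume(shape=(20, 20, 10), spacing=0.5, density=None, phantom_hu=None):
    """Uniform-HU volume with two small phantom blocks in a corner."""
    hu = np.zeros(shape)
    phantoms = []
    specs = phantom_hu or [(0.0, 0.0), (800.0, 0.8)]
    for i, (hu_val, rho) in enumerate(specs):
        mask = np.zeros(shape, dtype=bool)
        mask[2 * i : 2 * i + 2, 0:2, :] = True
        hu[mask] = hu_val
        phantoms.append(ct.PhantomInsert(label=f"p{i}", density=rho, mask=mask))
    if density is not None:
        body = np.ones(shape, dtype=bool)
        for p in phantoms:
            body &= ~p.mask
        hu[body] = density * 1000.0  # matches the two-point 0.001 slope line
    return VoxelVolume(
        hu=hu,
        spacing=(spacing, spacing, spacing),
        defect_span=(0.0, shape[2] * spacing),
        phantoms=phantoms,
    )


class TestCalibration:
    def test_two_point_line_exact(self):
        cal = cm.calibrate_hu_to_bmd(block_volume())
        assert cal.slope == pytest.approx(0.001, rel=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-15)
        assert cal.r_squared == pytest.approx(1.0)

    def test_collinear_phantoms_recovered_to_machine_precision(self):
        specs = [((rho + 0.05) / 0.0008, rho) for rho in (0, 0.1, 0.2, 0.4, 0.6, 0.8)]
        vol = block_volume(phantom_hu=specs)
        cal = cm.calibrate_hu_to_bmd(vol)
        assert cal.slope == pytest.approx(0.0008, rel=1e-12)
        assert cal.intercept == pytest.approx(-0.05, abs=1e-12)

    def test_noisy_phantoms_slope_within_2pct_of_normal_equations(self):
        rng = np.random.default_rng(11)
        densities = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8)
        true_slope = 0.0008
        specs = []
        for rho in densities:
            specs.append((rho / true_slope + rng.normal(0, 2.0), rho))
        vol = block_volume(shape=(20, 20, 10), phantom_hu=specs)
        cal = cm.calibrate_hu_to_bmd(vol)
        # independent oracle: normal equations on the exact same region means
        x = np.array([vol.hu[p.mask].mean() for p in vol.phantoms])
        y = np.array([p.density for p in vol.phantoms])
        slope_oracle = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert cal.slope == pytest.approx(slope_oracle, rel=1e-12)
        assert abs(cal.slope / true_slope - 1) < 0.02

    def test_degenerate_designs_raise(self):
        vol = block_volume(phantom_hu=[(100.0, 0.1), (100.0, 0.5)])
        with pytest.raises(CalibrationError):
            cm.calibrate_hu_to_bmd(vol)
        single = block_volume()
        single.phantoms = single.phantoms[:1]
        with pytest.raises(CalibrationError):
            cm.calibrate_hu_to_bmd(single)

    def test_phantom_density_outside_range_rejected(self):
        with pytest.raises(ValueError, match="0, 0.8"):
            ct.PhantomInsert(label="x", density=1.0, mask=np.ones((2, 2, 2), bool))


class TestSegmentation:
    def test_uniform_above_and_below_threshold(self):
        cal = cm.calibrate_hu_to_bmd(block_volume())
        dense = block_volume(density=1.25)
        mask = cm.segment_mineralized(dense, cal)
        body = ~dense.phantom_union_mask()
        assert mask[body].all() and not mask[~body].any()
        empty = cm.segment_mineralized(block_volume(density=0.0), cal)
        assert not empty.any()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        vol = block_volume()
        vol.hu += rng.uniform(0, 1500, vol.hu.shape)
        cal = cm.CalibrationLine(slope=0.001, intercept=0.0, r_squared=1.0)
        csa_low = cm.csa_profile(cm.segment_mineralized(vol, cal, 0.2), vol.spacing)
        csa_high = cm.csa_profile(cm.segment_mineralized(vol, cal, 0.5), vol.spacing)
        assert np.all(csa_high <= csa_low)


def cylinder_volume(radius_mm, spacing, extent=16.0, nz=10, hu_inside=1250.0):
    n = int(round(2 * extent / spacing))
    origin = (-extent, -extent, 0.0)
    hu = np.zeros((n, n, nz))
    x = origin[0] + (np.arange(n) + 0.5) * spacing
    y = origin[1] + (np.arange(n) + 0.5) * spacing
    disk = (x[:, None] ** 2 + y[None, :] ** 2) <= radius_mm**2
    hu[disk, :] = hu_inside
    return VoxelVolume(
        hu=hu, spacing=(spacing, spacing, spacing),
        defect_span=(0.0, nz * spacing), origin=origin,
    )


CAL = cm.CalibrationLine(slope=0.001, intercept=0.0, r_squared=1.0)


class TestProfiles:
    def test_cylinder_csa_within_2pct(self):
        vol = cylinder_volume(6.789, 0.3)
        csa = cm.csa_profile(cm.segment_mineralized(vol, CAL), vol.spacing)
        assert np.allclose(csa, csa[0])
        assert csa[0] == pytest.approx(np.pi * 6.789**2, rel=0.02)

    def test_resolution_convergence(self):
        # the staircase error oscillates with the exact radius/spacing
        # ratio, so compare mean absolute error over a spread of radii
        radii = np.linspace(5.0, 8.0, 7)
        errs = []
        for spacing in (0.9, 0.3):
            err = [
                abs(
                    cm.csa_profile(
                        cm.segment_mineralized(cylinder_volume(r, spacing, nz=4), CAL),
                        (spacing, spacing, spacing),
                    )[0]
                    - np.pi * r**2
                )
                for r in radii
            ]
            errs.append(np.mean(err))
        assert errs[1] < errs[0]

    def test_empty_slice_zero_and_step_profile(self):
        vol = cylinder_volume(6.0, 0.3, nz=20)
        # overwrite upper half with a smaller cylinder
        small = cylinder_volume(3.0, 0.3, nz=20)
        vol.hu[:, :, 10:] = small.hu[:, :, 10:]
        vol.hu[:, :, 5] = 0.0  # knock out one slice entirely
        csa = cm.csa_profile(cm.segment_mineralized(vol, CAL), vol.spacing)
        assert csa[5] == 0.0
        assert csa[0] == pytest.approx(np.pi * 36, rel=0.03)
        assert csa[15] == pytest.approx(np.pi * 9, rel=0.05)
        assert csa[15] < csa[0]


class TestTotalVolume:
    def test_rectangle_rule(self):
        z = (np.arange(70) + 0.5) * 0.5  # 35 mm of slices
        csa = np.full(70, 120.0)
        tv = cm.total_volume(z, csa, 0.5, defect_span=(10.0, 25.0), margin_mm=10.0)
        assert tv == pytest.approx(35.0 * 120.0 / 1000.0)

    def test_empty_mask_zero(self):
        z = (np.arange(10) + 0.5) * 1.0
        assert cm.total_volume(z, np.zeros(10), 1.0, (2.0, 8.0), 1.0) == 0.0

    def test_additivity_over_abutting_windows(self):
        rng = np.random.default_rng(2)
        z = (np.arange(100) + 0.5) * 0.3
        csa = rng.uniform(50, 200, 100)
        left = cm.total_volume(z, csa, 0.3, (3.0, 12.0), 0.0)
        right = cm.total_volume(z, csa, 0.3, (12.0, 27.0), 0.0)
        both = cm.total_volume(z, csa, 0.3, (3.0, 27.0), 0.0)
        assert left + right == pytest.approx(both, rel=1e-12)

    def test_clipped_window_warns(self):
        z = (np.arange(10) + 0.5) * 1.0
        with pytest.warns(UserWarning, match="clipping"):
            cm.total_volume(z, np.ones(10), 1.0, (0.0, 10.0), margin_mm=10.0)


class TestBmdProfile:
    def test_uniform_density_recovered(self):
        vol = cylinder_volume(6.0, 0.5, hu_inside=1250.0)
        mask = cm.segment_mineralized(vol, CAL)
        per_slice, summary = cm.bmd_profile(vol, mask, CAL)
        assert summary == pytest.approx(1.25)
        assert np.nanmax(np.abs(per_slice - 1.25)) < 1e-12

    def test_two_regions_mean(self):
        vol = cylinder_volume(6.0, 0.5, nz=10, hu_inside=500.0)
        vol.hu[vol.hu > 0] = 500.0
        half = vol.hu.shape[0] // 2
        upper = vol.hu[half:, :, :]
        upper[upper > 0] = 1000.0
        mask = cm.segment_mineralized(vol, CAL)
        # equal-size halves at 0.5 and 1.0 -> 0.75 per slice
        per_slice, summary = cm.bmd_profile(vol, mask, CAL)
        assert summary == pytest.approx(0.75, abs=0.02)

    def test_empty_slices_are_missing_not_zero(self):
        vol = cylinder_volume(6.0, 0.5, nz=10)
        vol.hu[:, :, 3] = 0.0
        mask = cm.segment_mineralized(vol, CAL)
        per_slice, _ = cm.bmd_profile(vol, mask, CAL)
        assert np.isnan(per_slice[3])

    def test_fully_empty_span_warns_nan(self):
        vol = cylinder_volume(6.0, 0.5, nz=10, hu_inside=10.0)
        mask = cm.segment_mineralized(vol, CAL)
        with pytest.warns(UserWarning):
            _, summary = cm.bmd_profile(vol, mask, CAL)
        assert np.isnan(summary)


class TestContralateralNormalization:
    @staticmethod
    def profile(csa, bmd, span=(0.0, 15.0), tv=None):
        n = 30
        z = (np.arange(n) + 0.5) * 0.5
        return cm.MorphometryProfile(
            z_mm=z, csa_mm2=np.full(n, csa), bmd_g_cm3=np.full(n, bmd),
            defect_span=span, tv_cm3=tv if tv is not None else csa * 15.0 / 1000.0,
            csa_mean_mm2=csa, bmd_mean_g_cm3=bmd,
        )

    def test_identical_profiles_are_100(self):
        p = self.profile(144.79, 1.25)
        out = cm.normalize_to_contralateral(p, p)
        assert out == pytest.approx({"tv_pct": 100.0, "csa_pct": 100.0, "bmd_pct": 100.0})

    def test_doubled_csa_is_200(self):
        treated = self.profile(2 * 144.79, 1.25)
        control = self.profile(144.79, 1.25)
        assert cm.normalize_to_contralateral(treated, control)["csa_pct"] == pytest.approx(200.0)

    def test_designed_overgrowth_recovered(self):
        # design a treated TV of 347.88 % of the 2.17 cm^3 control reference
        control = self.profile(144.79, 1.25)
        designed_tv = 3.4788 * 144.79 * 15.0 / 1000.0
        treated = self.profile(200.0, 0.8, tv=designed_tv)
        out = cm.normalize_to_contralateral(treated, control)
        assert out["tv_pct"] == pytest.approx(347.88, rel=1e-6)

    def test_zero_control_rejected(self):
        treated = self.profile(100.0, 1.0)
        control = self.profile(100.0, 0.0)
        with pytest.raises(ValueError, match="bmd_pct"):
            cm.normalize_to_contralateral(treated, control)


class TestNiftiIo:
    def test_round_trip_with_sidecar(self, tmp_path, truth):
        vol = cm.simulate_ct_volume(truth, 30, spacing=0.9)
        nii, side = tmp_path / "v.nii.gz", tmp_path / "v.json"
        ct.save_volume(vol, nii, side)
        back = ct.load_volume(nii, side)
        np.testing.assert_allclose(back.hu, vol.hu, rtol=1e-5)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.defect_span == pytest.approx(vol.defect_span)
        assert len(back.phantoms) == len(vol.phantoms)
        for a, b in zip(back.phantoms, vol.phantoms):
            assert a.density == b.density
            np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(back.roi_mask, vol.roi_mask)
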