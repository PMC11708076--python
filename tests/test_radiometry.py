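import numpy as np
import pytest

import whiskbroom as wb
from whiskbroom.acquisition import DarkRecord, PixelRecord, ScanCube, ScanPlan
from whiskbroom.calibration import CalibrationRecord
from whiskbroom.instrument import make_reference_scene
from whiskbroom.radiometry import (
    RadianceCube,
    ReceptorSet,
    band_integral,
    cone_catch,
    cube_to_radiance,
    extended_channels,
    render_extended,
    render_ndvi,
    render_saturation_mask,
    render_srgb,
    scene_peak_ratio,
    spectrum_at,
    to_reflectance,
)
from whiskbroom.spectral import DarkFrame, RawFrame
from conftest import hdr_plan


def _true_record(model):
    return CalibrationRecord(
        unit_id=0,
        wavelength_cal=model.wavelength_cal,
        lin_a=model.nonlinearity_a,
        lin_b=model.nonlinearity_b,
        sensitivity=model.sensitivity,
    )


def _radiance_cube(data, wavelengths=None):
    data = np.asarray(data, dtype=float)
    wl = np.linspace(320, 880, data.shape[-1]) if wavelengths is None else wavelengths
    shape = data.shape[:2]
    return RadianceCube(
        wavelengths=wl,
        data=data,
        saturated=np.zeros(shape, dtype=bool),
        interpolated=np.zeros(shape, dtype=bool),
    )


class TestCubeToRadiance:
    def test_noise_free_round_trip(self, instrument_exact, flat_scene):
        plan = ScanPlan(0, 36, 4, 0, 30, 10)
        cube = wb.run_scan(instrument_exact, flat_scene, plan)
        rcube = cube_to_radiance(cube, _true_record(instrument_exact))
        true_le = flat_scene.radiance_fn(0, 0).interpolated_to(rcube.wavelengths)
        for (row, col), rec in cube.pixels.items():
            got = rcube.data[row, col]
            np.testing.assert_allclose(got, true_le, rtol=1e-4)

    def test_zero_count_pixel_zero_radiance(self, instrument_noisefree):
        scene = make_reference_scene("flat", level=0.0)
        plan = ScanPlan(0, 0, 1, 0, 0, 1)
        cube = wb.run_scan(instrument_noisefree, scene, plan)
        rcube = cube_to_radiance(cube, _true_record(instrument_noisefree))
        np.testing.assert_array_equal(np.nan_to_num(rcube.data[0, 0]), 0.0)

    def test_exposure_invariance_two_times(self, instrument_exact, flat_scene, pose):
        m = instrument_exact
        frames = {t: wb.expose(m, flat_scene, pose, t) for t in (8000, 64000)}
        darks = [
            DarkRecord(after_row=0, frame=wb.dark_position_expose(m, t)) for t in (8000, 64000)
        ]
        plan = ScanPlan(0, 1, 1, 0, 0, 1)
        cube = ScanCube(
            plan=plan,
            pixels={
                (0, 0): PixelRecord(frame=frames[8000]),
                (0, 1): PixelRecord(frame=frames[64000]),
            },
            darks=darks,
            wavelength_cal=m.wavelength_cal,
        )
        rcube = cube_to_radiance(cube, _true_record(m))
        np.testing.assert_allclose(rcube.data[0, 0], rcube.data[0, 1], rtol=1e-6)

    def test_linearity_in_scene_radiance(self, instrument_exact):
        plan = ScanPlan(0, 4, 4, 0, 0, 1)
        cubes = {}
        for lvl in (0.05, 0.10):
            m = wb.default_instrument(0).noiseless()
            m.quantise = False
            scene = make_reference_scene("flat", level=lvl)
            cubes[lvl] = cube_to_radiance(wb.run_scan(m, scene, plan), _true_record(m))
        np.testing.assert_allclose(
            2.0 * cubes[0.05].data, cubes[0.10].data, rtol=1e-6
        )

    def test_missing_dark_error_names_time(self, instrument_noisefree, flat_scene):
        plan = ScanPlan(0, 0, 1, 0, 0, 1)
        cube = wb.run_scan(instrument_noisefree, flat_scene, plan)
        cube.darks.clear()
        t = cube.pixels[(0, 0)].integration_time
        with pytest.raises(LookupError, match=str(t)):
            cube_to_radiance(cube, _true_record(instrument_noisefree))

    def test_undefined_sensitivity_masked(self, instrument_noisefree, flat_scene):
        plan = ScanPlan(0, 0, 1, 0, 0, 1)
        cube = wb.run_scan(instrument_noisefree, flat_scene, plan)
        rec = _true_record(instrument_noisefree)
        rec.sensitivity = rec.sensitivity.copy()
        rec.sensitivity[:10] = np.nan
        rcube = cube_to_radiance(cube, rec)
        assert np.all(np.isnan(rcube.data[0, 0, :10]))
        assert np.all(np.isfinite(rcube.data[0, 0, 10:]))


class TestReflectance:
    def test_standard_pixel_is_100_percent(self):
        data = np.stack([[np.full(50, 2.0), np.full(50, 1.0)]])
        rc = _radiance_cube(data)
        refl = to_reflectance(rc, (0, 0))
        np.testing.assert_allclose(refl[0, 0], 100.0)
        np.testing.assert_allclose(refl[0, 1], 50.0)

    def test_standard_reflectance_factor(self):
        data = np.stack([[np.full(50, 2.0), np.full(50, 1.0)]])
        refl = to_reflectance(_radiance_cube(data), (0, 0), standard_reflectance=0.99)
        np.testing.assert_allclose(refl[0, 0], 99.0)

    def test_saturated_standard_rejected(self):
        rc = _radiance_cube(np.ones((1, 2, 50)))
        rc.saturated[0, 0] = True
        with pytest.raises(ValueError, match="saturated"):
            to_reflectance(rc, (0, 0))

    def test_interpolated_standard_rejected(self):
        rc = _radiance_cube(np.ones((1, 2, 50)))
        rc.interpolated[0, 0] = True
        with pytest.raises(ValueError, match="interpolated"):
            to_reflectance(rc, (0, 0))

    def test_near_zero_standard_masked(self):
        std = np.ones(50)
        std[:5] = 0.0
        data = np.stack([[std, np.full(50, 0.5)]])
        refl = to_reflectance(_radiance_cube(data), (0, 0))
        assert np.all(np.isnan(refl[0, 1, :5]))
        np.testing.assert_allclose(refl[0, 1, 5:], 50.0)

    def test_pastel_reflectance_recovery(self):
        """Simulator round trip: illuminant x known reflectances."""
        from whiskbroom.instrument import _SCENE_GRID, _gauss, _planck_shape
        from whiskbroom.instrument import SceneModel
        from whiskbroom.spectral import Spectrum

        m = wb.default_instrument(5)
        illum = 0.25 * _planck_shape(_SCENE_GRID, 5500.0)
        refls = [0.2 + 0.6 * _gauss(_SCENE_GRID, 650, 80), np.full_like(_SCENE_GRID, 0.99)]

        def rad_fn(az, el):
            return Spectrum(_SCENE_GRID, illum * refls[0 if az < 5 else 1], kind="radiance")

        cube = wb.run_scan(m, SceneModel(rad_fn), ScanPlan(0, 57, 57, 0, 0, 1))
        rcube = cube_to_radiance(cube, _true_record(m))
        refl = to_reflectance(rcube, (0, 1), standard_reflectance=0.99)
        wl = rcube.wavelengths
        sel = (wl >= 350) & (wl <= 750)
        true = np.interp(wl, _SCENE_GRID, 100 * refls[0])
        assert np.nanmax(np.abs(refl[0, 0] - true)[sel]) < 1.0  # within 1%


class TestRenderSrgb:
    def test_zero_cube_black(self):
        img = render_srgb(_radiance_cube(np.zeros((2, 3, 50))))
        assert img.shape == (2, 3, 3)
        assert img.dtype == np.uint8
        assert img.max() == 0

    def test_equal_energy_neutral_grey(self):
        img = render_srgb(_radiance_cube(np.ones((2, 2, 200))))
        px = img[0, 0].astype(float)
        assert px.max() > 0
        assert (px.max() - px.min()) / px.max() < 0.02

    def test_monochromatic_450nm_blue_dominant(self):
        wl = np.linspace(320, 880, 200)
        data = np.zeros((1, 1, 200))
        data[0, 0, np.argmin(np.abs(wl - 450))] = 1.0
        img = render_srgb(_radiance_cube(data, wl))
        r, g, b = img[0, 0].astype(int)
        assert b > r and b > g

    def test_output_range_uint8(self):
        rng = np.random.default_rng(0)
        img = render_srgb(_radiance_cube(rng.random((4, 5, 120)) * 100))
        assert img.dtype == np.uint8  # uint8 => [0, 255] by construction


class TestRenderExtended:
    def _mono_cube(self, centre):
        wl = np.linspace(320, 880, 400)
        data = np.zeros((1, 1, 400))
        data[0, 0] = np.exp(-0.5 * ((wl - centre) / 8) ** 2)
        return _radiance_cube(data, wl)

    def test_uv_only_blue_dominant(self):
        img = render_extended(self._mono_cube(350.0))
        r, g, b = img[0, 0].astype(int)
        assert b > r and b > g

    def test_nir_only_red_dominant(self):
        img = render_extended(self._mono_cube(800.0))
        r, g, b = img[0, 0].astype(int)
        assert r > g and r > b

    def test_broadband_channels_match_band_integral_oracle(self):
        wl = np.linspace(320, 880, 300)
        rng = np.random.default_rng(3)
        data = rng.random((2, 2, 300))
        rc = _radiance_cube(data, wl)
        ch = extended_channels(rc)
        from whiskbroom.cmf import xyz_cmf

        for (r, c) in ((0, 0), (1, 1)):
            le = data[r, c]
            nir = np.trapezoid(np.where((wl >= 750) & (wl <= 850), le, 0.0), wl)
            uv = np.trapezoid(np.where((wl >= 320) & (wl <= 400), le, 0.0), wl)
            y = np.trapezoid(le * xyz_cmf(wl)[:, 1], wl)
            # trapezoid-weight vs masked-trapezoid edge treatment differs by
            # at most one half-sample at the band edges
            assert ch[r, c, 0] == pytest.approx(nir, rel=0.02)
            assert ch[r, c, 2] == pytest.approx(uv, rel=0.02)
            assert ch[r, c, 1] == pytest.approx(y, rel=1e-6)


class TestSaturationMask:
    def test_all_false_when_unsaturated(self, instrument_noisefree, flat_scene):
        cube = wb.run_scan(instrument_noisefree, flat_scene, ScanPlan(0, 4, 4, 0, 0, 1))
        assert not render_saturation_mask(cube).any()

    def test_hdr_sources_saturating_at_minimum(self, hdr_scene):
        m = wb.default_instrument(0, sensitivity=np.full(288, 3.0)).noiseless()
        cube = wb.run_scan(m, hdr_scene, hdr_plan())
        mask = render_saturation_mask(cube)
        flags = np.zeros_like(mask)
        for (row, col), rec in cube.pixels.items():
            flags[row, col] = rec.frame.saturated
        np.testing.assert_array_equal(mask, flags)
        assert mask.sum() == flags.sum() > 0


class TestNdvi:
    def test_red_equals_nir_gives_zero(self):
        wl = np.linspace(320, 880, 1200)
        data = np.zeros((1, 1, 1200))
        data[0, 0, (wl >= 620) & (wl <= 700)] = 1.0
        data[0, 0, (wl >= 750) & (wl <= 850)] = 1.0
        rc = _radiance_cube(data, wl)
        # equalise band integrals exactly, then NDVI must vanish
        nir = band_integral(rc, 750, 850)[0, 0]
        red = band_integral(rc, 620, 700)[0, 0]
        data[0, 0, (wl >= 750) & (wl <= 850)] *= red / nir
        assert render_ndvi(_radiance_cube(data, wl))[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_nir_only_gives_plus_one(self):
        wl = np.linspace(320, 880, 300)
        data = np.zeros((1, 1, 300))
        data[0, 0, (wl >= 760) & (wl <= 840)] = 1.0
        assert render_ndvi(_radiance_cube(data, wl))[0, 0] == pytest.approx(1.0)

    def test_zero_over_zero_is_zero(self):
        assert render_ndvi(_radiance_cube(np.zeros((1, 1, 300))))[0, 0] == 0.0

    def test_red_edge_matches_band_integral_oracle(self):
        wl = np.linspace(320, 880, 300)
        vegetation = 0.05 + 0.45 / (1.0 + np.exp(-(wl - 715.0) / 10.0))  # red-edge step
        rc = _radiance_cube(vegetation[None, None, :], wl)
        nir = band_integral(rc, 750, 850)[0, 0]
        red = band_integral(rc, 620, 700)[0, 0]
        assert render_ndvi(rc)[0, 0] == pytest.approx((nir - red) / (nir + red), rel=1e-9)

    def test_bounds_always_respected(self):
        rng = np.random.default_rng(9)
        ndvi = render_ndvi(_radiance_cube(rng.random((5, 5, 120)) * 1e4))
        assert np.all(ndvi >= -1.0) and np.all(ndvi <= 1.0)


class TestConeCatch:
    def _receptors(self, wl):
        return ReceptorSet(
            wavelengths=wl,
            receptors={
                "lw": np.exp(-0.5 * ((wl - 560) / 40) ** 2),
                "sw": np.exp(-0.5 * ((wl - 440) / 30) ** 2),
            },
        )

    def test_zero_radiance_zero_catch(self):
        wl = np.linspace(320, 880, 200)
        catches = cone_catch(_radiance_cube(np.zeros((2, 2, 200)), wl), self._receptors(wl))
        for img in catches.values():
            np.testing.assert_array_equal(img, 0.0)

    def test_disjoint_support_zero(self):
        wl = np.linspace(320, 880, 400)
        data = np.zeros((1, 1, 400))
        data[0, 0, wl > 800] = 1.0  # emission far from both receptors
        catches = cone_catch(_radiance_cube(data, wl), self._receptors(wl))
        assert catches["sw"][0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_trapezoid_oracle(self):
        wl = np.linspace(320, 880, 400)
        data = np.zeros((1, 1, 400))
        data[0, 0] = np.exp(-0.5 * ((wl - 560) / 5) ** 2)  # narrowband at LW peak
        rset = self._receptors(wl)
        catches = cone_catch(_radiance_cube(data, wl), rset)
        oracle = np.trapezoid(data[0, 0] * wl * rset.receptors["lw"], wl)
        assert catches["lw"][0, 0] == pytest.approx(oracle, rel=1e-6)

    def test_additive_and_homogeneous(self):
        wl = np.linspace(320, 880, 150)
        rng = np.random.default_rng(4)
        a, b = rng.random((2, 1, 1, 150))
        rset = self._receptors(wl)
        ca = cone_catch(_radiance_cube(a, wl), rset)["lw"]
        cb = cone_catch(_radiance_cube(b, wl), rset)["lw"]
        cab = cone_catch(_radiance_cube(a + b, wl), rset)["lw"]
        c3a = cone_catch(_radiance_cube(3 * a, wl), rset)["lw"]
        assert cab[0, 0] == pytest.approx(ca[0, 0] + cb[0, 0], rel=1e-9)
        assert c3a[0, 0] == pytest.approx(3 * ca[0, 0], rel=1e-9)

    def test_no_overlap_error(self):
        wl = np.linspace(320, 880, 100)
        rset = ReceptorSet(
            wavelengths=np.linspace(1000, 1100, 10), receptors={"ir": np.ones(10)}
        )
        with pytest.raises(ValueError, match="overlap"):
            cone_catch(_radiance_cube(np.ones((1, 1, 100)), wl), rset)

    def test_receptor_csv_round_trip(self, tmp_path):
        path = tmp_path / "sensitivity_data.csv"
        wl = np.arange(300, 701, 100)
        path.write_text(
            "wavelength_nm,uv,lw\n"
            + "\n".join(f"{w},{0.1 * i},{0.2 * i}" for i, w in enumerate(wl))
        )
        rset = ReceptorSet.from_csv(path)
        assert set(rset.receptors) == {"uv", "lw"}
        np.testing.assert_allclose(rset.wavelengths, wl)
        np.testing.assert_allclose(rset.receptors["lw"], 0.2 * np.arange(5))


class TestScenePeakRatio:
    def test_flat_scene_ratio_one(self):
        assert scene_peak_ratio(_radiance_cube(np.ones((2, 3, 50)))) == pytest.approx(1.0)

    def test_interpolated_pixels_excluded(self):
        data = np.ones((1, 3, 50))
        data[0, 1] = 1000.0
        rc = _radiance_cube(data)
        rc.interpolated[0, 1] = True
        assert scene_peak_ratio(rc) == pytest.approx(1.0)

    def test_degenerate_min_reported_inf(self):
        data = np.ones((1, 2, 50))
        data[0, 1] = 0.0
        with pytest.warns(UserWarning, match="inf"):
            assert scene_peak_ratio(_radiance_cube(data)) == np.inf

    def test_needs_two_measured_pixels(self):
        with pytest.raises(ValueError):
            scene_peak_ratio(_radiance_cube(np.ones((1, 1, 50))))


def test_spectrum_at_and_export(tmp_path):
    rc = _radiance_cube(np.ones((1, 1, 50)) * 2.0)
    spec = spectrum_at(rc, (0, 0))
    assert spec.kind == "radiance"
    from whiskbroom.radiometry import export_spectrum_csv

    out = tmp_path / "spec.csv"
    export_spectrum_csv(out, spec.wavelengths, spec.values, "radiance")
    lines = out.read_text().splitlines()
    assert lines[0] == "wavelength_nm,radiance"
    assert len(lines) == 51
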