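"""Annulus machinery and the four peripapillary metrics."""

import dataclasses

import numpy as np
import pytest

import psoct_iop as P
from psoct_iop.errors import ConfigurationError, InvalidInputError
from psoct_iop.quantify import (
    AnnulusSpec,
    EnFaceMap,
    SlabSpec,
    annulus_average,
    annulus_mask,
    depression_map,
    hemifield_split,
    reflectivity_ratio_map,
    rnfl_retardation,
    scleral_birefringence_map,
)
from psoct_iop.segment import NoiseEstimate, Surface, estimate_noise_floor


def _geom(n=256, pitch=5.859375, n_z=10):
    return P.VolumeGeometry(n_z, n, n, lateral_pitch_x=pitch, lateral_pitch_y=pitch)


class TestAnnulusMask:
    def test_full_disk_when_inner_tiny_outer_huge(self):
        g = _geom(n=8, pitch=10.0)
        mask = annulus_mask(AnnulusSpec((35.0, 35.0), 1e-4, 1e6), g)
        assert mask.all()

    def test_area_matches_analytic(self):
        g = _geom()
        spec = AnnulusSpec((750.0, 750.0), 550.0, 870.0)
        mask = annulus_mask(spec, g)
        analytic = np.pi * (435.0**2 - 275.0**2) / (g.lateral_pitch_x * g.lateral_pitch_y)
        assert mask.sum() == pytest.approx(analytic, rel=0.02)

    def test_matches_bruteforce(self):
        g = _geom()
        spec = AnnulusSpec((750.0, 750.0), 300.0, 700.0)
        mask = annulus_mask(spec, g)
        count = 0
        for ix in range(g.n_x):
            for iy in range(g.n_y):
                r = np.hypot(ix * g.lateral_pitch_x - 750.0, iy * g.lateral_pitch_y - 750.0)
                count += 150.0 <= r < 350.0
        assert mask.sum() == count

    def test_annulus_outside_field_rejected(self):
        with pytest.raises(ConfigurationError):
            annulus_mask(AnnulusSpec((5000.0, 5000.0), 300.0, 700.0), _geom(n=32, pitch=10.0))


class TestAnnulusAverage:
    def _map(self, values, g):
        return EnFaceMap(values, np.isfinite(values), g)

    def test_constant_map(self):
        g = _geom(n=64, pitch=23.4375)
        res = annulus_average(self._map(np.full((64, 64), 3.5), g), AnnulusSpec((750, 750), 300, 700))
        assert res.mean == pytest.approx(3.5)
        assert res.sd == pytest.approx(0.0)
        assert not res.excluded

    def test_half_nan_exclusion(self):
        g = _geom(n=64, pitch=23.4375)
        vals = np.full((64, 64), 1.0)
        vals[:, : 32] = np.nan
        res = annulus_average(self._map(vals, g), AnnulusSpec((750, 750), 300, 700), valid_fraction_min=0.6)
        assert res.excluded
        assert res.n_valid > 0

    def test_checkerboard_mean(self):
        g = _geom(n=128, pitch=11.71875)
        ix, iy = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        vals = np.where((ix + iy) % 2 == 0, 1.0, 3.0)
        spec = AnnulusSpec((750, 750), 550, 870)
        res = annulus_average(self._map(vals, g), spec)
        n = annulus_mask(spec, g).sum()
        assert abs(res.mean - 2.0) <= 1.0 / n * 2 + 0.01

    def test_rotation_invariance_for_symmetric_map(self):
        """Annulus means of a radially symmetric map are unchanged by 90-degree
        rotation about the ONH centre (within pixelation tolerance)."""
        g = _geom(n=128, pitch=11.71875)
        ix, iy = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        r = np.hypot(ix * g.lateral_pitch_x - 750.0, iy * g.lateral_pitch_y - 750.0)
        vals = 1.0 + np.exp(-r / 300.0)
        spec = AnnulusSpec((750.0, 750.0), 550, 870)
        m0 = annulus_average(EnFaceMap(vals, np.isfinite(vals), g), spec).mean
        # rotate about the pixel-grid centre; the annulus centre moves by <1 px
        rot = np.rot90(vals)
        m1 = annulus_average(EnFaceMap(rot, np.isfinite(rot), g), spec).mean
        assert m1 == pytest.approx(m0, rel=0.02)


class TestDepression:
    def test_zero_for_identical_volumes(self):
        g = _geom(n=32, pitch=23.4375, n_z=200)
        base = Surface(np.full((32, 32), 100.0), g)
        cur = Surface(np.full((32, 32), 100.0), g, registered=True)
        dep = depression_map(cur, base)
        assert np.allclose(dep.values, 0.0)

    def test_unregistered_rejected(self):
        g = _geom(n=16, pitch=23.4375, n_z=200)
        s = Surface(np.full((16, 16), 100.0), g)
        with pytest.raises(InvalidInputError):
            depression_map(s, s)

    def test_positive_means_posterior(self):
        g = _geom(n=16, pitch=23.4375, n_z=200)
        base = Surface(np.full((16, 16), 100.0), g)
        cur = Surface(np.full((16, 16), 105.0), g, registered=True)
        dep = depression_map(cur, base)
        assert np.allclose(dep.values, 5.0 * g.axial_pitch)


def _flat_volume(n_z, n_xy, layers, geometry=None):
    """Stack of constant-intensity layers; layers = [(z0, z1, value), ...]."""
    g = geometry or P.VolumeGeometry(n_z, n_xy, n_xy, lateral_pitch_x=20.0, lateral_pitch_y=20.0)
    lin = np.zeros(g.shape)
    for z0, z1, v in layers:
        lin[z0:z1] = v
    return P.ReflectivityVolume(lin, g)


class TestReflectivityRatio:
    def test_uniform_volume_gives_one(self):
        refl = _flat_volume(200, 16, [(0, 200, 2.0)])
        g = refl.geometry
        ilm = Surface(np.full((16, 16), 50.0), g)
        rpe = Surface(np.full((16, 16), 150.0), g)
        emap = reflectivity_ratio_map(refl, ilm, rpe)
        assert np.allclose(emap.values, 1.0)

    def test_known_ratio_and_scale_invariance(self):
        refl = _flat_volume(200, 16, [(50, 70, 4.0), (70, 150, 2.0)])
        g = refl.geometry
        ilm = Surface(np.full((16, 16), 50.0), g)
        rpe = Surface(np.full((16, 16), 150.0), g)
        emap = reflectivity_ratio_map(refl, ilm, rpe)
        assert np.allclose(emap.values, 2.0)
        scaled = P.ReflectivityVolume(refl.linear_intensity * 37.0, g)
        emap2 = reflectivity_ratio_map(scaled, ilm, rpe)
        assert np.allclose(emap2.values, emap.values)

    def test_missing_rpe_gives_nan(self):
        refl = _flat_volume(200, 16, [(0, 200, 1.0)])
        g = refl.geometry
        ilm = Surface(np.full((16, 16), 50.0), g)
        z = np.full((16, 16), 150.0)
        z[3, 4] = np.nan
        emap = reflectivity_ratio_map(refl, ilm, Surface(z, g))
        assert np.isnan(emap.values[3, 4])
        assert np.isfinite(emap.values[0, 0])

    def test_noiseless_phantom_matches_response_exactly(self, flat_noiseless_cfg):
        vol, truth = P.generate_volume(flat_noiseless_cfg, 30, seed=0)
        refl = P.compute_reflectivity(vol)
        emap = reflectivity_ratio_map(refl, truth.ilm_surface, truth.rpe_surface)
        assert np.nanmax(np.abs(emap.values - truth.reflectivity_ratio)) < 1e-5


class TestRnflRetardation:
    def test_noiseless_phantom_nine_degrees(self, clean_vol):
        vol, truth = clean_vol
        refl = P.compute_reflectivity(vol)
        noise = estimate_noise_floor(refl, truth.ilm_surface)
        ret = P.compensate_corneal(P.compute_retardation(vol), truth.ilm_surface)
        g = vol.geometry
        ann = AnnulusSpec((g.n_x / 2 * g.lateral_pitch_x, g.n_y / 2 * g.lateral_pitch_y), 550, 870)
        res = rnfl_retardation(ret, refl, truth.ilm_surface, noise, ann)
        assert res.mean == pytest.approx(truth.rnfl_retardation, abs=0.2)
        assert not res.excluded

    def test_uncompensated_rejected(self, clean_vol):
        vol, truth = clean_vol
        refl = P.compute_reflectivity(vol)
        noise = estimate_noise_floor(refl, truth.ilm_surface)
        ret = P.compute_retardation(vol)
        g = vol.geometry
        ann = AnnulusSpec((g.n_x / 2 * g.lateral_pitch_x, g.n_y / 2 * g.lateral_pitch_y), 550, 870)
        with pytest.raises(InvalidInputError):
            rnfl_retardation(ret, refl, truth.ilm_surface, noise, ann)

    def test_all_below_threshold_excluded(self, clean_vol):
        vol, truth = clean_vol
        refl = P.compute_reflectivity(vol)
        ret = P.compensate_corneal(P.compute_retardation(vol), truth.ilm_surface)
        g = vol.geometry
        ann = AnnulusSpec((g.n_x / 2 * g.lateral_pitch_x, g.n_y / 2 * g.lateral_pitch_y), 550, 870)
        loud = NoiseEstimate(mean_floor_db=0.0)  # floor above every tissue voxel
        res = rnfl_retardation(ret, refl, truth.ilm_surface, loud, ann)
        assert res.excluded
        assert res.n_valid == 0


class TestScleralBirefringence:
    def _ramp_volume(self, slope_deg_px, n_z=120, n_xy=8, rpe=40.0):
        g = P.VolumeGeometry(n_z, n_xy, n_xy, lateral_pitch_x=20.0, lateral_pitch_y=20.0)
        z = np.arange(n_z, dtype=float)[:, None, None]
        delta = np.clip(slope_deg_px * (z - (rpe + 20.0)), 0.0, 89.9)
        amp = np.ones(g.shape)
        vol = P.PSVolume(amp * np.cos(np.radians(delta)), amp * np.sin(np.radians(delta)), g)
        ret = P.compute_retardation(vol)
        ret.compensated = True  # analytic construction carries no corneal offset
        refl = P.compute_reflectivity(vol)
        return ret, refl, Surface(np.full((n_xy, n_xy), rpe), g)

    def test_linear_ramp_closed_form(self):
        # 0.5 deg/px at 1.9 um/px -> 0.26316 deg/um
        ret, refl, rpe = self._ramp_volume(0.5)
        emap = scleral_birefringence_map(ret, refl, rpe, NoiseEstimate(-50.0))
        assert np.allclose(emap.values, 0.5 / 1.9, atol=1e-9)

    def test_constant_retardation_zero_slope(self):
        ret, refl, rpe = self._ramp_volume(0.0)
        emap = scleral_birefringence_map(ret, refl, rpe, NoiseEstimate(-50.0))
        assert np.allclose(emap.values, 0.0, atol=1e-12)

    def test_slab_beyond_volume_is_nan(self):
        ret, refl, rpe_s = self._ramp_volume(0.1, n_z=120)
        deep = Surface(np.full((8, 8), 100.0), ret.geometry)
        emap = scleral_birefringence_map(ret, refl, deep, NoiseEstimate(-50.0))
        assert np.all(np.isnan(emap.values))

    def test_noiseless_phantom_oracle_equality(self, flat_noiseless_cfg):
        """On a flat noiseless phantom the per-A-scan fit returns the generator
        ramp slope exactly (up to float32 amplitude quantisation)."""
        vol, truth = P.generate_volume(flat_noiseless_cfg, 45, seed=0)
        ret = P.compensate_corneal(P.compute_retardation(vol), truth.ilm_surface)
        emap = scleral_birefringence_map(
            ret, P.compute_reflectivity(vol), truth.rpe_surface, NoiseEstimate(-200.0)
        )
        assert np.nanmax(np.abs(emap.values - truth.scleral_birefringence)) < 1e-4


class TestHemifield:
    def _map_and_annulus(self, vals):
        g = _geom(n=64, pitch=23.4375)
        spec = AnnulusSpec((750.0, 750.0), 550, 870)
        return EnFaceMap(vals, np.isfinite(vals), g), spec

    def test_symmetric_constant_map(self):
        emap, spec = self._map_and_annulus(np.full((64, 64), 2.0))
        sup, inf = hemifield_split(emap, spec)
        assert sup.mean() == pytest.approx(inf.mean())

    def test_signed_hemifields(self):
        g = _geom(n=64, pitch=23.4375)
        iy = np.arange(64)[None, :] * g.lateral_pitch_y
        vals = np.where(np.broadcast_to(iy, (64, 64)) >= 750.0, 1.0, -1.0)
        emap, spec = self._map_and_annulus(vals)
        sup, inf = hemifield_split(emap, spec)
        assert sup.mean() == pytest.approx(1.0)
        assert inf.mean() == pytest.approx(-1.0)

    def test_null_phantom_rarely_significant(self, small_cfg):
        """With no built-in hemifield asymmetry the rank-sum test on scleral
        birefringence pixels is non-significant in >= 90% of seeds."""
        import psoct_iop.stats as S

        n_sig = 0
        seeds = range(8)
        for seed in seeds:
            vol, truth = P.generate_volume(small_cfg, 55, seed=1000 + seed)
            res = P.process_volume(vol, None, None)
            sup, inf = hemifield_split(res["scleral_birefringence_map"], res["metric_annulus"])
            n_sig += S.wilcoxon_ranksum(sup, inf) < 0.05
        assert n_sig <= 1


class TestSlabSpec:
    def test_thickness_um(self):
        g = P.VolumeGeometry(100, 4, 4, axial_pitch=1.9)
        assert SlabSpec("RPE", 20, 40).thickness_um(g) == pytest.approx(76.0)

    def test_invalid_slabs_rejected(self):
        with pytest.raises(ConfigurationError):
            SlabSpec("ILM", -1, 20)
        with pytest.raises(ConfigurationError):
            SlabSpec("ILM", 0, 0)
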