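"""FTIR chain: normalization, integration, clustering, deconvolution, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from sklearn.metrics import adjusted_rand_score

from stromakit import ftir
from stromakit import synthetic as syn
from stromakit.errors import (
    DegenerateClusteringError,
    DegenerateSpectrumError,
    EmptyClusterError,
    MissingBandError,
    ParameterError,
    WindowError,
)
from stromakit.types import BandSpec, BandWindow, Spectrum, WavenumberAxis


def _axis():
    return WavenumberAxis.from_range(1800, 900, 4.0)


class TestVectorNormalize:
    def test_constant_spectrum_unit_norm(self):
        ax = WavenumberAxis.from_range(1800, 1404, 4.0)  # 100 points
        s = ftir.vector_normalize(Spectrum(ax, np.full(100, 2.0)))
        # constant c over n points maps to 1/sqrt(n), giving unit norm
        assert np.allclose(s.absorbance, 0.1)
        assert np.linalg.norm(s.absorbance) == pytest.approx(1.0)

    def test_scale_invariance(self):
        ax = _axis()
        rng = np.random.default_rng(0)
        y = rng.random(len(ax))
        a = ftir.vector_normalize(Spectrum(ax, y))
        b = ftir.vector_normalize(Spectrum(ax, 2.0 * y))
        assert np.allclose(a.absorbance, b.absorbance)

    def test_cube_pixel_norms_unit(self):
        cube, _ = syn.make_two_class_cube((8, 8), noise_sd=0.02, seed=1)
        n = ftir.vector_normalize(cube)
        norms = np.linalg.norm(n.absorbance, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            ftir.vector_normalize(Spectrum(_axis(), np.zeros(len(_axis()))))


class TestIntegrateBand:
    def test_unit_absorbance_area_is_window_width(self):
        ax = _axis()
        s = Spectrum(ax, np.ones(len(ax)))
        area = ftir.integrate_band(s, BandWindow(1720.0, 1470.0))
        assert area == pytest.approx(250.0)

    def test_gaussian_area_matches_closed_form(self):
        ax = _axis()
        band = BandSpec(1550.0, 1.3, 12.0)
        area = ftir.integrate_band(Spectrum(ax, band.profile(ax.values)),
                                   BandWindow(1720.0, 1470.0))
        assert area == pytest.approx(band.area, rel=0.01)

    def test_inverted_window_rejected(self):
        with pytest.raises(WindowError):
            BandWindow(1470.0, 1720.0)

    def test_window_outside_axis_rejected(self):
        ax = WavenumberAxis.from_range(1500, 1100, 4.0)
        with pytest.raises(WindowError):
            ftir.integrate_band(Spectrum(ax, np.ones(len(ax))), BandWindow(1720.0, 1470.0))


class TestHCA:
    def test_k1_single_label(self):
        cube, _ = syn.make_two_class_cube((8, 8))
        cm = ftir.hca_ward(cube, 1)
        assert np.all(cm.labels == 1)

    def test_noiseless_two_class_exact_recovery(self, two_class_cube_clean):
        cube, truth = two_class_cube_clean
        cm = ftir.hca_ward(cube, 2)
        ari = adjusted_rand_score(truth.class_map.ravel(), cm.labels.ravel())
        assert ari == 1.0

    def test_recovery_degrades_monotonically_with_noise(self):
        aris = []
        for noise in (0.02, 0.3, 1.0):
            cube, truth = syn.make_two_class_cube((16, 16), noise_sd=noise, seed=6)
            cm = ftir.hca_ward(ftir.vector_normalize(cube), 2)
            aris.append(adjusted_rand_score(truth.class_map.ravel(), cm.labels.ravel()))
        assert aris[0] >= 0.99
        assert aris[0] >= aris[1] >= aris[2]

    def test_collagen_label_points_to_rich_class(self, two_class_cube_clean):
        cube, truth = two_class_cube_clean
        cm = ftir.hca_ward(cube, 2)
        rich_pixels = cm.labels == cm.collagen_label
        assert np.array_equal(rich_pixels, truth.class_map == 1)

    def test_zero_variance_rejected(self):
        cm = np.ones((4, 4), dtype=int)
        cube, _ = syn.make_hypercube(cm, {1: (BandSpec(1280.0, 1.0, 8.0),)})
        with pytest.raises(DegenerateClusteringError):
            ftir.hca_ward(cube, 2)


class TestClusterMean:
    def test_single_pixel_cluster_is_that_spectrum(self):
        cube, _ = syn.make_two_class_cube((4, 4), noise_sd=0.05, seed=2)
        labels = np.ones((4, 4), dtype=int)
        labels[0, 0] = 2
        from stromakit.types import ClusterMap

        cm = ClusterMap(labels, 2, 1)
        s = ftir.cluster_mean_spectrum(cube, cm, 2)
        assert np.array_equal(s.absorbance, cube.absorbance[0, 0])

    def test_noisy_mean_within_clt_bound(self):
        cube, truth = syn.make_two_class_cube((46, 46), noise_sd=0.05, seed=3)
        from stromakit.types import ClusterMap

        cm = ClusterMap(truth.class_map, 2, 1)
        mean1 = ftir.cluster_mean_spectrum(cube, cm, 1)
        template = sum(b.profile(cube.axis.values) for b in truth.band_tables[1])
        n = (truth.class_map == 1).sum()
        bound = 3.0 * 0.05 / np.sqrt(n)
        assert np.all(np.abs(mean1.absorbance - template) < bound * 3)

    def test_empty_label_rejected(self):
        cube, truth = syn.make_two_class_cube((4, 4))
        from stromakit.types import ClusterMap

        cm = ClusterMap(np.ones((4, 4), int), 2, 1)
        with pytest.raises(EmptyClusterError):
            ftir.cluster_mean_spectrum(cube, cm, 2)


class TestSecondDerivative:
    def test_single_gaussian_minimum_at_centroid(self):
        ax = _axis()
        band = BandSpec(1280.0, 1.0, 8.0)
        d2 = ftir.second_derivative(Spectrum(ax, band.profile(ax.values)))
        wn_min = ax.values[np.argmin(d2.absorbance)]
        assert abs(wn_min - 1280.0) <= ax.step

    def test_straight_line_zero(self):
        ax = _axis()
        y = 0.01 * ax.values + 3.0
        d2 = ftir.second_derivative(Spectrum(ax, y))
        assert np.all(np.abs(d2.absorbance) < 1e-9)

    def test_two_band_resolution(self):
        ax = WavenumberAxis.from_range(1400, 1100, 2.0)
        y = BandSpec(1280.0, 1.0, 8.0).profile(ax.values) + BandSpec(
            1240.0, 1.0, 8.0
        ).profile(ax.values)
        d2 = ftir.second_derivative(Spectrum(ax, y))
        minima = ftir.band_minima(d2, BandWindow(1360.0, 1184.0))
        assert any(abs(mn - 1280.0) <= 2.0 for mn in minima)
        assert any(abs(mn - 1240.0) <= 2.0 for mn in minima)

    def test_invalid_window_rejected(self):
        with pytest.raises(ParameterError):
            ftir.second_derivative(Spectrum(_axis(), np.zeros(len(_axis()))), 4, 3)


class TestFitGaussians:
    def test_single_band_exact_recovery(self):
        ax = _axis()
        band = BandSpec(1550.0, 0.8, 10.0)
        pm = ftir.fit_gaussians(
            Spectrum(ax, band.profile(ax.values)), BandWindow(1720.0, 1470.0), [1550.0]
        )
        c = pm.components[0]
        assert c.centroid_cm1 == pytest.approx(1550.0, abs=1e-2)
        assert c.height == pytest.approx(0.8, rel=1e-3)
        assert c.sigma_cm1 == pytest.approx(10.0, rel=1e-3)

    def test_tricuspid_triplet_recovery(self):
        ax = WavenumberAxis.from_range(1800, 900, 4.0)
        bands = [BandSpec(c, 1.0, 10.0) for c in (1280.0, 1240.0, 1205.0)]
        y = sum(b.profile(ax.values) for b in bands)
        y = y + np.random.default_rng(5).normal(0, 0.01, y.shape)
        pm = ftir.fit_gaussians(
            Spectrum(ax, y), BandWindow(1360.0, 1184.0), [1280.0, 1240.0, 1205.0]
        )
        for band in bands:
            comp = pm.nearest(band.centroid_cm1, 6.0)
            assert abs(comp.centroid_cm1 - band.centroid_cm1) <= 1.0
            assert comp.area == pytest.approx(band.area, rel=0.05)

    def test_all_zero_spectrum_flagged(self):
        ax = _axis()
        pm = ftir.fit_gaussians(
            Spectrum(ax, np.zeros(len(ax))), BandWindow(1360.0, 1184.0), [1280.0]
        )
        assert pm.flags == ["all_zero_input"]
        assert all(c.height == 0 for c in pm.components)

    def test_area_conservation_low_noise(self):
        bands = syn.collagen_band_table()
        ax = _axis()
        y = sum(b.profile(ax.values) for b in bands)
        spec = Spectrum(ax, y)
        pm = ftir.fit_gaussians(
            spec, BandWindow(1360.0, 1184.0),
            [1342.0, 1319.0, 1280.0, 1262.0, 1240.0, 1205.0],
        )
        window_area = ftir.integrate_band(spec, BandWindow(1360.0, 1184.0))
        assert pm.total_area == pytest.approx(window_area, rel=0.05)


class TestRatioPanel:
    def _panel_for(self, bands, **kw):
        ax = _axis()
        y = sum(b.profile(ax.values) for b in bands)
        spec = Spectrum(ax, y)
        pm = ftir.fit_gaussians(
            spec, BandWindow(1360.0, 1184.0),
            [b.centroid_cm1 for b in bands if b.centroid_cm1 <= 1360.0],
        )
        return ftir.ratio_panel(spec, pm, **kw)

    def test_planted_mixture_matches_analytic_quotients(self):
        bands = syn.collagen_band_table()
        truth = syn.analytic_ratio_panel(bands)
        panel = self._panel_for(bands)
        for k, v in truth.as_dict().items():
            assert panel.as_dict()[k] == pytest.approx(v, rel=0.05)

    def test_scale_invariance(self):
        bands = syn.collagen_band_table()
        scaled = [BandSpec(b.centroid_cm1, 3.7 * b.height, b.sigma_cm1) for b in bands]
        a = self._panel_for(bands).as_dict()
        b = self._panel_for(scaled).as_dict()
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-3)

    def test_amide_only_spectrum_misses_amide3_bands(self):
        bands = [BandSpec(1655.0, 1.0, 18.0), BandSpec(1550.0, 0.7, 16.0)]
        ax = _axis()
        y = sum(b.profile(ax.values) for b in bands)
        spec = Spectrum(ax, y)
        pm = ftir.fit_gaussians(spec, BandWindow(1360.0, 1184.0), [1280.0])
        with pytest.raises(MissingBandError):
            ftir.ratio_panel(spec, pm)

    def test_component_sum_numerator_option(self):
        bands = syn.collagen_band_table()
        panel = self._panel_for(bands, collagen_numerator="components")
        tri = sum(
            b.area for b in bands if b.centroid_cm1 in (1280.0, 1240.0, 1205.0)
        )
        prt = syn.bands_window_area(bands, (1720.0, 1470.0))
        assert panel.coll_prt == pytest.approx(tri / prt, rel=0.05)


class TestRegionPipeline:
    def test_collagen_rich_region_scores_higher(self):
        rich, _ = syn.make_two_class_cube((16, 16), collagen_scale_rich=1.0)
        poor, _ = syn.make_two_class_cube((16, 16), collagen_scale_rich=0.45)
        p_rich = ftir.region_pipeline(rich).panel
        p_poor = ftir.region_pipeline(poor).panel
        assert p_rich.coll_prt > p_poor.coll_prt

    def test_noiseless_panel_matches_truth(self, two_class_cube_clean):
        cube, truth = two_class_cube_clean
        panel = ftir.region_pipeline(cube).panel.as_dict()
        expected = truth.panels[1].as_dict()
        for k in expected:
            assert panel[k] == pytest.approx(expected[k], rel=0.02)

    def test_deterministic(self):
        cube, _ = syn.make_two_class_cube((12, 12), noise_sd=0.01, seed=9)
        a = ftir.region_pipeline(cube).panel.as_dict()
        b = ftir.region_pipeline(cube).panel.as_dict()
        assert a == b


@settings(max_examples=5, derandomize=True, deadline=None)
@given(hst.floats(min_value=0.05, max_value=10.0))
def test_panel_scale_invariance_property(scale):
    """Every ratio is invariant under positive scaling of the spectra."""
    bands = syn.collagen_band_table()
    ax = WavenumberAxis.from_range(1800, 900, 4.0)
    y = sum(b.profile(ax.values) for b in bands)
    for y_use in (y, scale * y):
        spec = Spectrum(ax, y_use)
        pm = ftir.fit_gaussians(
            spec, BandWindow(1360.0, 1184.0),
            [1342.0, 1319.0, 1280.0, 1262.0, 1240.0, 1205.0],
        )
        panel = ftir.ratio_panel(spec, pm)
        if y_use is y:
            base = panel.as_dict()
        else:
            for k, v in base.items():
                assert panel.as_dict()[k] == pytest.approx(v, rel=1e-3)
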