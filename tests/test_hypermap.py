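"""Chemical maps, coarse-to-fine localization, diffraction optics."""

import math

import numpy as np
import pytest

from ramanlipids.errors import LocalizationError, ValidationError
from ramanlipids.hypermap import (BandImage, band_image, component_maps,
                                  default_lipid_band, lateral_resolution,
                                  locate_lipid_region, spot_size)
from ramanlipids.synth import Droplet, Patch, Scene, sample_hypercube


class TestOptics:
    @pytest.mark.parametrize("ex, expected", [(532, 0.811), (785, 1.197)])
    def test_spot_size_printed_values(self, ex, expected):
        assert spot_size(ex, 0.8) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("ex, expected", [(532, 0.279), (785, 0.412)])
    def test_lateral_resolution_printed_values(self, ex, expected):
        assert lateral_resolution(ex, 0.8) == pytest.approx(expected, abs=5e-4)

    def test_closed_form_arithmetic(self):
        assert spot_size(800.0, 0.976) == pytest.approx(1.000, abs=1e-3)

    def test_doubling_na_halves_resolution(self):
        assert lateral_resolution(532, 1.4) == pytest.approx(
            lateral_resolution(532, 0.7) / 2.0, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            spot_size(532, 0.0)
        with pytest.raises(ValidationError):
            spot_size(-5, 0.8)
        with pytest.raises(ValidationError):
            lateral_resolution(532, 2.0)


def droplet_scene(x=7.0, y=3.0, radius=1.0, **kw):
    return Scene(extent=(20.0, 20.0), droplets=[Droplet(x, y, radius)], **kw)


class TestBandImage:
    def test_identical_spectra_give_constant_image(self):
        scene = Scene(extent=(20.0, 20.0), background_lipid=1.0)
        cube = sample_hypercube(scene, (10.0, 10.0), 8.0, 4, 532, seed=0)
        img = band_image(cube, (1380.0, 1500.0))
        assert np.ptp(img.values) <= 1e-9 * abs(img.values).max()

    def test_band_outside_grid_rejected(self):
        cube = sample_hypercube(droplet_scene(), (10.0, 10.0), 8.0, 4, 532)
        with pytest.raises(ValidationError):
            band_image(cube, (3000.0, 4000.0))

    def test_droplet_pixel_is_maximum(self):
        cube = sample_hypercube(droplet_scene(), (10.0, 10.0), 20.0, 10, 532,
                                seed=0)
        img = band_image(cube, default_lipid_band(532))
        ix, iy = img.argmax_pixel()
        assert cube.pixel_center(ix, iy) == (7.0, 3.0)

    def test_lipid_and_carotenoid_maxima_disjoint(self):
        scene = droplet_scene(patches=[Patch(15.0, 15.0, 1.5, carotenoid=30.0)])
        cube = sample_hypercube(scene, (10.0, 10.0), 20.0, 10, 532, seed=0)
        lip = band_image(cube, default_lipid_band(532))
        car = band_image(cube, (1505.0, 1535.0))
        assert lip.argmax_pixel() != car.argmax_pixel()

    def test_total_scales_linearly_with_concentration(self):
        totals = []
        for conc in (1.0, 3.0):
            scene = Scene(extent=(20.0, 20.0),
                          droplets=[Droplet(10.0, 10.0, 1.5,
                                            concentration=conc)])
            cube = sample_hypercube(scene, (10.0, 10.0), 10.0, 6, 532, seed=0)
            totals.append(band_image(cube, default_lipid_band(532)).values.sum())
        assert totals[1] == pytest.approx(3.0 * totals[0], rel=1e-6)

    def test_tie_break_lowest_row_column(self):
        vals = np.zeros((3, 3))
        vals[1, 2] = 5.0
        vals[2, 0] = 5.0
        img = BandImage(vals, (0.0, 1.0))
        assert img.argmax_pixel() == (2, 1)  # row 1 beats row 2


class TestComponentMaps:
    def test_lipid_only_scene_labels_lipid_where_signal(self):
        cube = sample_hypercube(droplet_scene(10.0, 10.0, 1.5), (10.0, 10.0),
                                10.0, 10, 532, seed=0)
        maps = component_maps(cube)
        assert maps.labels.max() == 3
        assert set(np.unique(maps.labels)) <= {0, 3}

    def three_patch_cube(self, scale=1.0):
        scene = Scene(extent=(12.0, 12.0),
                      droplets=[Droplet(3.0, 3.0, 1.2,
                                        concentration=scale)],
                      patches=[Patch(9.0, 3.0, 1.2, carotenoid=30.0 * scale),
                               Patch(3.0, 9.0, 1.2, protein=30.0 * scale)])
        return sample_hypercube(scene, (6.0, 6.0), 12.0, 12, 532, seed=0,
                                noise_sd=0.5 * scale)

    def test_three_patches_recovered(self):
        maps = component_maps(self.three_patch_cube())
        assert maps.labels[3, 3] == 3   # lipid droplet at (3, 3)
        assert maps.labels[3, 9] == 2   # carotenoid patch at (9, 3)
        assert maps.labels[9, 3] == 1   # protein patch at (3, 9)

    def test_composite_invariant_to_global_rescale(self):
        a = component_maps(self.three_patch_cube(1.0))
        b = component_maps(self.three_patch_cube(50.0))
        # same geometry at 50x intensity: identical labelling
        assert np.array_equal(a.labels, b.labels)


class TestLocate:
    def test_converges_to_planted_droplet(self):
        res = locate_lipid_region(droplet_scene(), (10.0, 10.0), 20.0,
                                  seed=1, noise_sd=2.0)
        assert math.hypot(res.center[0] - 7.0, res.center[1] - 3.0) < 0.5
        assert res.n_iterations == math.ceil(math.log2(20.0 / 1.0))

    def test_iteration_count_exact_power_of_two(self):
        res = locate_lipid_region(droplet_scene(), (10.0, 10.0), 16.0,
                                  seed=1)
        assert res.n_iterations == 4

    def test_both_laser_band_selections_succeed(self):
        for ex in (532, 785):
            res = locate_lipid_region(droplet_scene(), (10.0, 10.0), 20.0,
                                      excitation_nm=ex, seed=2, noise_sd=1.0)
            assert math.hypot(res.center[0] - 7.0, res.center[1] - 3.0) < 0.5

    def test_brighter_droplet_wins(self):
        scene = Scene(extent=(20.0, 20.0),
                      droplets=[Droplet(5.4, 5.4, 1.0, concentration=1.0),
                                Droplet(14.6, 14.6, 1.0, concentration=2.0)])
        res = locate_lipid_region(scene, (10.0, 10.0), 20.0, seed=3)
        assert math.hypot(res.center[0] - 14.6, res.center[1] - 14.6) < 0.5

    def test_uniform_scene_fails(self):
        scene = Scene(extent=(20.0, 20.0), background_lipid=1.0)
        with pytest.raises(LocalizationError):
            locate_lipid_region(scene, (10.0, 10.0), 20.0, seed=1)

    def test_monotone_convergence_noise_free(self):
        res = locate_lipid_region(droplet_scene(6.3, 11.2), (10.0, 10.0),
                                  20.0, seed=0)
        dists = [math.hypot(c[0] - 6.3, c[1] - 11.2)
                 for _, c, _ in res.trace]
        # never moves away from the truth between iterations beyond the
        # half-pixel-diagonal quantization of the finer map
        for d_prev, d_next, (_, _, w) in zip(dists, dists[1:], res.trace[1:]):
            assert d_next <= d_prev + (w / 10.0) * math.sqrt(2.0) / 2.0

    def test_result_invariant_to_start_center(self):
        a = locate_lipid_region(droplet_scene(), (10.0, 10.0), 20.0, seed=0)
        b = locate_lipid_region(droplet_scene(), (8.0, 6.0), 16.0, seed=0)
        assert math.hypot(a.center[0] - b.center[0],
                          a.center[1] - b.center[1]) < 0.3

    def test_bad_windows_rejected(self):
        with pytest.raises(ValidationError):
            locate_lipid_region(droplet_scene(), (10.0, 10.0), 0.5,
                                stop_window=1.0)
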