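"""Generator contracts: band structure, laser regimes, bleaching, scenes."""

import math

import numpy as np
import pytest

from ramanlipids import synth
from ramanlipids.errors import ValidationError
from ramanlipids.synth import (CellProfile, Droplet, Scene, analytic_ratio,
                               sample_hypercube, simulate_cell,
                               simulate_standard)


def region_max(s, lo, hi):
    return float(np.max(s.intensities[s.window_slice(lo, hi)]))


def test_deterministic_under_seed(oleic):
    a = simulate_standard(oleic, 532, noise_sd=5.0, seed=42)
    b = simulate_standard(oleic, 532, noise_sd=5.0, seed=42)
    assert np.array_equal(a.intensities, b.intensities)


def test_distinct_seeds_differ_only_within_noise(oleic):
    a = simulate_standard(oleic, 532, noise_sd=5.0, seed=1)
    b = simulate_standard(oleic, 532, noise_sd=5.0, seed=2)
    diff = a.intensities - b.intensities
    assert np.std(diff) == pytest.approx(5.0 * math.sqrt(2), rel=0.1)


def test_unsupported_excitation_rejected(oleic):
    with pytest.raises(ValidationError):
        simulate_standard(oleic, 633)


def test_ratio_contract_doubles_with_unsaturation():
    c18_1 = analytic_ratio(1, 14, 532)
    c18_2 = analytic_ratio(2, 12, 532)
    assert c18_1 == pytest.approx(7.3 / 14)
    assert c18_2 == pytest.approx(7.3 / 12 * 2)


def test_laser_intensity_order_of_magnitude(oleic):
    """Dominant-peak intensities differ by roughly 10x between lasers."""
    s532 = simulate_standard(oleic, 532)
    s785 = simulate_standard(oleic, 785)
    ratio = s532.intensities.max() / s785.intensities.max()
    assert 5 < ratio < 20


def test_ch_stretch_dominance_by_laser(stearic):
    s532 = simulate_standard(stearic, 532)
    s785 = simulate_standard(stearic, 785)
    assert region_max(s532, 2800, 3000) > region_max(s532, 1380, 1500)
    assert region_max(s785, 2800, 3000) < region_max(s785, 1380, 1500)


def test_fluorescence_bleach_decay_factor():
    """Baseline amplitude drops by exp(-t/tau) with tau = 25 s."""
    prof = CellProfile(lipid_amount=0.0, carotenoid=0.0, chlorophyll=0.0)
    s0 = simulate_cell(prof, bleach_seconds=0, noise_sd=0)
    s75 = simulate_cell(prof, bleach_seconds=75, noise_sd=0)
    i0 = s0.intensities[s0.window_slice(2197, 2203)].mean()
    i75 = s75.intensities[s75.window_slice(2197, 2203)].mean()
    assert i0 / i75 == pytest.approx(math.exp(75 / 25), rel=1e-9)


def test_carotenoid_band_bleaches_fast():
    """Resonance carotenoid bands decay with their own, shorter time
    constant (10 s)."""
    prof = CellProfile(lipid_amount=0.0, chlorophyll=0.0, fluorescence=0.0)
    s0 = simulate_cell(prof, bleach_seconds=0, noise_sd=0)
    s30 = simulate_cell(prof, bleach_seconds=30, noise_sd=0)
    i0 = region_max(s0, 1515, 1525)
    i30 = region_max(s30, 1515, 1525)
    assert i0 / i30 == pytest.approx(math.exp(30.0 / 10.0), rel=1e-9)


def test_negative_profile_weights_rejected():
    with pytest.raises(ValidationError):
        CellProfile(carotenoid=-1.0)
    with pytest.raises(ValidationError):
        CellProfile(lipids=[(synth._OLEIC, -0.5)])


def test_droplet_outside_extent_rejected():
    with pytest.raises(ValidationError):
        Scene(extent=(10.0, 10.0), droplets=[Droplet(12.0, 5.0, 1.0)])


class TestHypercubeSampling:
    def scene(self):
        return Scene(extent=(20.0, 20.0), droplets=[Droplet(10.0, 10.0, 1.5)])

    def test_uniform_scene_gives_flat_band_image(self):
        from ramanlipids.hypermap import band_image
        scene = Scene(extent=(20.0, 20.0), background_lipid=0.5)
        cube = sample_hypercube(scene, (10.0, 10.0), 10.0, 5, 532, seed=0)
        img = band_image(cube, (2800.0, 3000.0))
        assert np.ptp(img.values) <= 1e-6 * abs(img.values).max()

    def test_central_droplet_maximizes_center_pixel(self):
        from ramanlipids.hypermap import band_image
        cube = sample_hypercube(self.scene(), (10.0, 10.0), 10.0, 10, 532,
                                seed=0)
        img = band_image(cube, (2800.0, 3000.0))
        # droplet at scene centre; 10x10 grid puts it between the two
        # central pixel rows/columns
        ix, iy = img.argmax_pixel()
        assert ix in (4, 5) and iy in (4, 5)

    def test_finer_window_resolves_droplet_with_more_pixels(self):
        from ramanlipids.hypermap import band_image
        counts = []
        for window in (10.0, 5.0):
            cube = sample_hypercube(self.scene(), (10.0, 10.0), window, 10,
                                    532, seed=0)
            vals = band_image(cube, (2800.0, 3000.0)).values
            counts.append(int((vals > 0.5 * vals.max()).sum()))
        # halving the window quadruples pixel density over the droplet
        assert 2.5 < counts[1] / counts[0] < 6.5

    def test_sampling_repeatable_and_resampleable(self):
        cube1 = sample_hypercube(self.scene(), (10.0, 10.0), 8.0, 4, 532,
                                 seed=3, noise_sd=2.0)
        cube2 = sample_hypercube(self.scene(), (10.0, 10.0), 8.0, 4, 532,
                                 seed=3, noise_sd=2.0)
        assert np.array_equal(cube1.intensities, cube2.intensities)

    def test_window_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            cube = sample_hypercube(self.scene(), (1.0, 1.0), 10.0, 4, 532)
        assert cube.origin == (0.0, 0.0)

    def test_bad_window_rejected(self):
        with pytest.raises(ValidationError):
            sample_hypercube(self.scene(), (10.0, 10.0), 0.0, 4, 532)
        with pytest.raises(ValidationError):
            sample_hypercube(self.scene(), (10.0, 10.0), 10.0, 1, 532)
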