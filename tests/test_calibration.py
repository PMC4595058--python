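"""Calibration fitting, inversion, mixtures, and population classes."""

import numpy as np
import pytest

from ramanlipids import synth
from ramanlipids.calibration import (CalibrationModel, classify_population,
                                     double_bonds_from_ratio, fit_linear,
                                     fit_sigmoid_mp, mixture_ratio, quantify,
                                     standard_calibration)
from ramanlipids.errors import RangeError, ValidationError
from ramanlipids.fatty_acids import standard_registry, unsaturation_ratio
from ramanlipids.preprocess import subtract_background
from ramanlipids.reference import ALGAL_ISOLATES, isolate_calibration


def test_exact_line_fit():
    pts = [(x, 2.0 * x) for x in (0.0, 1.0, 2.5, 4.0)]
    m = fit_linear(pts)
    assert m.params["slope"] == pytest.approx(2.0, abs=1e-12)
    assert m.params["intercept"] == pytest.approx(0.0, abs=1e-12)
    assert m.r_squared == pytest.approx(1.0)


def test_degenerate_x_rejected():
    with pytest.raises(ValidationError):
        fit_linear([(1.0, 0.0), (1.0, 2.0)])


def test_isolate_table_ols_matches_hand_oracle():
    """OLS over the eight-strain table agrees with an independent
    closed-form least-squares computation."""
    x = ALGAL_ISOLATES["ratio_1650_1440"].to_numpy()
    y = ALGAL_ISOLATES["c_double_bonds"].to_numpy()
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    m = isolate_calibration()["c_bonds"]
    assert m.params["slope"] == pytest.approx(slope, rel=1e-12)
    assert m.params["intercept"] == pytest.approx(intercept, rel=1e-12)
    assert m.params["slope"] == pytest.approx(1.64, abs=0.01)
    assert m.params["intercept"] == pytest.approx(-0.045, abs=0.002)


def test_isolate_model_prediction_at_057():
    m = isolate_calibration()["c_bonds"]
    assert round(m.predict(0.57), 2) == 0.89


def test_linear_round_trip_inversion():
    m = fit_linear([(0.0, -0.5), (1.0, 1.7), (2.0, 3.9)])
    for x in (-3.0, 0.0, 0.7, 12.0):
        assert m.invert(m.predict(x)) == pytest.approx(x, rel=1e-9, abs=1e-9)
    for y in (-1.0, 0.3, 5.0):
        assert m.predict(m.invert(y)) == pytest.approx(y, rel=1e-9, abs=1e-9)


def test_model_text_round_trip():
    m = fit_linear([(0.0, 1.0), (1.0, 3.0)], excitation_nm=532)
    back = CalibrationModel.from_text(m.to_text())
    assert back.params == m.params
    assert back.excitation_nm == 532
    assert back.kind == "linear"


class TestSigmoid:
    def points(self):
        reg = standard_registry()
        return [(fa.melting_point,
                 synth.analytic_ratio(fa.n_double_bonds, fa.n_ch2, 532))
                for fa in reg]

    def test_fit_is_decreasing_with_good_r2(self):
        m = fit_sigmoid_mp(self.points(), 532, seed=0)
        xs = np.linspace(-60, 70, 200)
        ys = [m.predict(x) for x in xs]
        assert all(a >= b for a, b in zip(ys, ys[1:]))
        assert m.r_squared > 0.8

    def test_asymptote_has_no_finite_preimage(self):
        m = fit_sigmoid_mp(self.points(), 532, seed=0)
        with pytest.raises(RangeError):
            m.invert(m.params["upper"])
        with pytest.raises(RangeError):
            m.invert(m.params["lower"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_sigmoid_mp(self.points()[:4])


class TestMixtures:
    def test_pure_component(self, oleic):
        assert mixture_ratio([(oleic, 1.0)]) == pytest.approx(7.3 / 14.0)

    def test_fifty_fifty_between_pure_ratios(self, oleic, palmitoleic):
        r = mixture_ratio([(oleic, 0.5), (palmitoleic, 0.5)])
        m_o = 0.5 / oleic.molecular_weight
        m_p = 0.5 / palmitoleic.molecular_weight
        expected = 7.3 * (m_o + m_p) / (m_o * 14 + m_p * 12)
        assert r == pytest.approx(expected, rel=1e-12)
        assert 7.3 / 14.0 < r < 7.3 / 12.0

    def test_sweep_monotone(self, oleic, palmitoleic):
        rs = [mixture_ratio([(oleic, 1 - w), (palmitoleic, w)])
              for w in np.linspace(0, 1, 21)]
        assert all(a < b for a, b in zip(rs, rs[1:]))

    def test_unnormalized_weights_rejected(self, oleic, palmitoleic):
        with pytest.raises(ValidationError):
            mixture_ratio([(oleic, 0.6), (palmitoleic, 0.6)])
        with pytest.raises(ValidationError):
            mixture_ratio([(oleic, -0.2), (palmitoleic, 1.2)])


class TestQuantify:
    def models(self):
        models = isolate_calibration()
        models["mp"] = standard_calibration(532, seed=0)["mp"]
        return models

    def test_cc503_like_cell_quantifies_to_benchmark(self):
        models = self.models()
        quants = []
        for seed in range(3):  # replicate cells
            cell = synth.simulate_cell(seed=seed)
            quants.append(quantify(subtract_background(cell), models))
        for q in quants:
            assert q.r1650_1440 == pytest.approx(0.52, abs=0.05)
        est_c = np.mean([q.est_c_double_bonds for q in quants])
        est_n = np.mean([q.est_n_ratio for q in quants])
        assert est_c == pytest.approx(0.80, abs=0.05)
        assert est_n == pytest.approx(0.07, abs=0.01)

    def test_excitation_mismatch_rejected(self):
        cell = synth.simulate_cell(excitation_nm=785, seed=3)
        flat = subtract_background(cell)
        with pytest.raises(ValidationError, match="nm"):
            quantify(flat, self.models())

    def test_zero_ratio_clipped_to_zero_with_warning(self, stearic):
        s = synth.simulate_standard(stearic, 532, 0.0)
        with pytest.warns(UserWarning, match="clipped"):
            q = quantify(s, self.models())
        assert q.est_c_double_bonds == 0.0
        assert q.warnings


def test_double_bonds_from_ratio_exact(registry):
    for fa in registry:
        if fa.n_ch2 == 0:
            continue
        r = synth.analytic_ratio(fa.n_double_bonds, fa.n_ch2, 532)
        est = double_bonds_from_ratio(r, fa.n_ch2)
        assert est == pytest.approx(fa.n_double_bonds, abs=1e-12)


class TestClassifyPopulation:
    def test_wild_type_single_class(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.80, 0.05, size=30)
        _, counts = classify_population(vals.tolist())
        assert set(counts) == {"monounsaturated-dominant"}

    def test_mutant_panel_three_classes(self):
        rng = np.random.default_rng(1)
        modes = np.array([0.1, 0.5, 0.9])
        vals = (modes[rng.integers(0, 3, size=30)]
                + rng.normal(0, 0.05, size=30))
        _, counts = classify_population(vals.tolist())
        assert len(counts) == 3

    def test_identical_values_single_class_counts_preserved(self):
        labels, counts = classify_population([0.5] * 12)
        assert counts == {"mixed": 12}
        assert len(labels) == 12

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            classify_population([])
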