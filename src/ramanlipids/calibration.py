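"""Calibration relations and single-cell lipid quantitation.

Three calibrations map the measured intensity ratio I1650/I1440 onto lipid
properties:

* ratio <-> number of C=C bonds         (linear)
* ratio <-> N_C=C/N_CH2                 (linear)
* ratio <-> melting point               (4-parameter logistic, decreasing)

Linear models are ordinary least squares; the melting-point relation is a
four-parameter logistic fitted with seeded multi-start least squares and
inverted on its monotone branch.  ``quantify`` runs a spectrum through the
peak-fitting stage and applies all three models; ``classify_population``
bins per-cell double-bond estimates into saturated-dominant / mixed /
monounsaturated-dominant sub-populations.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError, RangeError, ValidationError
from .fatty_acids import FattyAcid, standard_registry, unsaturation_ratio
from .peakfit import IntensityRatios, intensity_ratios
from .spectrum import Spectrum

__all__ = [
    "CalibrationModel", "LipidQuant", "fit_linear", "fit_sigmoid_mp",
    "quantify", "mixture_ratio", "classify_population",
    "double_bonds_from_ratio", "standard_calibration",
    "CLASS_THRESHOLDS", "CLASS_LABELS",
]

#: est C=C thresholds separating saturated-dominant / mixed /
#: monounsaturated-dominant cells (midpoints between the 0 / ~0.5 / ~1
#: archetypes).
CLASS_THRESHOLDS = (0.35, 0.65)

CLASS_LABELS = ("saturated-dominant", "mixed", "monounsaturated-dominant")


@dataclass
class CalibrationModel:
    """A fitted, invertible mapping between intensity ratio and a property.

    ``kind`` is ``"linear"`` (params: slope, intercept) or ``"sigmoid4pl"``
    (params: lower, upper, midpoint, scale; y decreasing in x).
    """

    kind: str
    params: dict[str, float]
    x_semantics: str
    y_semantics: str
    r_squared: float
    n_points: int
    excitation_nm: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "sigmoid4pl"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        need = {"linear": {"slope", "intercept"},
                "sigmoid4pl": {"lower", "upper", "midpoint", "scale"}}[self.kind]
        if set(self.params) != need:
            raise ValidationError(f"{self.kind} model needs params {need}")
        if self.kind == "linear" and self.n_points < 2:
            raise ValidationError("linear model needs >= 2 points")
        if self.kind == "sigmoid4pl":
            if self.n_points < 5:
                raise ValidationError("sigmoid model needs >= 5 points")
            if self.params["upper"] <= self.params["lower"]:
                raise ValidationError("sigmoid upper asymptote must exceed lower")
            if self.params["scale"] <= 0:
                raise ValidationError("sigmoid scale must be > 0")

    def predict(self, x: float) -> float:
        if self.kind == "linear":
            return self.params["slope"] * x + self.params["intercept"]
        p = self.params
        return p["lower"] + (p["upper"] - p["lower"]) / (
            1.0 + math.exp((x - p["midpoint"]) / p["scale"]))

    def invert(self, y: float) -> float:
        """Preimage of ``y`` on the model's monotone branch.

        Raises
        ------
        RangeError
            For a degenerate linear slope, or a sigmoid value at/beyond an
            asymptote (no finite preimage).
        """
        if self.kind == "linear":
            if self.params["slope"] == 0:
                raise RangeError("cannot invert a zero-slope linear model")
            return (y - self.params["intercept"]) / self.params["slope"]
        p = self.params
        if not (p["lower"] < y < p["upper"]):
            raise RangeError(
                f"value {y:g} outside the sigmoid's open range "
                f"({p['lower']:g}, {p['upper']:g}); no finite preimage")
        return p["midpoint"] + p["scale"] * math.log(
            (p["upper"] - p["lower"]) / (y - p["lower"]) - 1.0)

    def to_text(self) -> str:
        lines = [f"kind: {self.kind}",
                 f"x_semantics: {self.x_semantics}",
                 f"y_semantics: {self.y_semantics}"]
        for k in sorted(self.params):
            lines.append(f"{k}: {self.params[k]:.12g}")
        lines += [f"r_squared: {self.r_squared:.12g}",
                  f"n_points: {self.n_points}",
                  f"excitation_nm: {self.excitation_nm}"]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CalibrationModel":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition(":")
            kv[k.strip()] = v.strip()
        kind = kv.pop("kind")
        x_sem = kv.pop("x_semantics")
        y_sem = kv.pop("y_semantics")
        r2 = float(kv.pop("r_squared"))
        n = int(kv.pop("n_points"))
        ex_raw = kv.pop("excitation_nm", "None")
        ex = None if ex_raw in ("None", "") else int(ex_raw)
        params = {k: float(v) for k, v in kv.items()}
        return cls(kind=kind, params=params, x_semantics=x_sem,
                   y_semantics=y_sem, r_squared=r2, n_points=n,
                   excitation_nm=ex)


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("points must be (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def fit_linear(points, x_semantics: str = "ratio_1650_1440",
               y_semantics: str = "property",
               excitation_nm: int | None = None) -> CalibrationModel:
    """Ordinary least squares y = slope*x + intercept.

    Raises
    ------
    ValidationError
        With fewer than 2 points or degenerate (constant) x.
    """
    x, y = _as_xy(points)
    if len(x) < 2:
        raise ValidationError("linear fit needs >= 2 points")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate x values: all equal")
    res = stats.linregress(x, y)
    return CalibrationModel(
        kind="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        x_semantics=x_semantics, y_semantics=y_semantics,
        r_squared=float(res.rvalue ** 2), n_points=len(x),
        excitation_nm=excitation_nm)


def _sigmoid(x, lower, upper, midpoint, scale):
    return lower + (upper - lower) / (1.0 + np.exp((x - midpoint) / scale))


def fit_sigmoid_mp(points, excitation_nm: int | None = None,
                   seed: int = 0, n_starts: int = 8,
                   weight_floor: float = 0.05) -> CalibrationModel:
    """Four-parameter logistic of intensity ratio against melting point.

    ``points`` are (melting_point_C, ratio) pairs; the fitted curve is
    decreasing in melting point (high ratio at low melting points).
    Responses span more than a decade, so the fit uses the relative
    weighting customary for 4PL calibration curves (per-point sigma
    proportional to the response, floored at ``weight_floor`` times the
    maximum so zero-response points keep finite weight).  Seeded
    multi-start least squares; the best converged fit with upper > lower
    asymptote is kept.

    Raises
    ------
    ValidationError
        With fewer than 5 points.
    FitError
        When no start converges to a monotone (upper > lower) curve.
    """
    x, y = _as_xy(points)
    if len(x) < 5:
        raise ValidationError("sigmoid fit needs >= 5 points")
    rng = np.random.default_rng(seed)
    span = float(np.ptp(x)) or 1.0
    sigma = np.maximum(y, weight_floor * float(np.max(y)))
    base = np.array([max(float(np.min(y)), 0.0), float(np.max(y)),
                     float(np.median(x)), span / 6.0])
    best, best_cost = None, np.inf
    for i in range(n_starts):
        p0 = base.copy()
        if i:
            p0 = p0 * rng.uniform(0.6, 1.4, size=4)
            p0[2] = base[2] + rng.uniform(-span / 3.0, span / 3.0)
        p0[3] = abs(p0[3]) or span / 6.0
        try:
            popt, _ = optimize.curve_fit(
                _sigmoid, x, y, p0=p0, sigma=sigma, absolute_sigma=False,
                bounds=([-np.inf, -np.inf, float(np.min(x)) - span,
                         1e-3], [np.inf, np.inf, float(np.max(x)) + span,
                                 10.0 * span]),
                maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = (y - _sigmoid(x, *popt)) / sigma
        cost = float(np.sum(resid ** 2))
        if popt[1] > popt[0] and cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        raise FitError("sigmoid fit failed: no monotone decreasing solution")
    ss_res = float(np.sum((y - _sigmoid(x, *best)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        kind="sigmoid4pl",
        params={"lower": float(best[0]), "upper": float(best[1]),
                "midpoint": float(best[2]), "scale": float(best[3])},
        x_semantics="melting_point_C", y_semantics="ratio_1650_1440",
        r_squared=r2, n_points=len(x), excitation_nm=excitation_nm)


@dataclass
class LipidQuant:
    """Quantified lipid properties of one spectrum."""

    r1650_1440: float
    r3003_1440: float
    est_c_double_bonds: float
    est_n_ratio: float
    est_melting_point: float
    excitation_nm: int
    warnings: list[str] = field(default_factory=list)


def _apply(model: CalibrationModel, ratio: float) -> float:
    """Evaluate a property model at a measured ratio, honouring which side
    of the calibration holds the ratio."""
    if model.x_semantics == "ratio_1650_1440":
        return model.predict(ratio)
    if model.y_semantics == "ratio_1650_1440":
        return model.invert(ratio)
    raise ValidationError(
        f"model maps {model.x_semantics} -> {model.y_semantics}; "
        "neither side is the intensity ratio")


def quantify(s: Spectrum, models: dict[str, CalibrationModel],
             noise_sd: float | None = None, *,
             skip_protein_screen: bool = False) -> LipidQuant:
    """Full quantitation of one background-subtracted spectrum.

    ``models`` holds ``c_bonds``, ``n_ratio`` and ``mp`` calibrations fitted
    for the spectrum's excitation wavelength (enforced via the excitation
    tag).  Negative property estimates are clipped to zero with a warning;
    a ratio outside the melting-point sigmoid's range yields NaN with a
    warning rather than an error.
    """
    for key in ("c_bonds", "n_ratio", "mp"):
        if key not in models:
            raise ValidationError(f"missing calibration model {key!r}")
        tag = models[key].excitation_nm
        if tag is not None and tag != s.excitation_nm:
            raise ValidationError(
                f"model {key!r} fitted for {tag} nm but spectrum recorded "
                f"at {s.excitation_nm} nm")
    ratios = intensity_ratios(s, noise_sd,
                              skip_protein_screen=skip_protein_screen)
    notes: list[str] = []

    est_c = _apply(models["c_bonds"], ratios.r1650_1440)
    est_n = _apply(models["n_ratio"], ratios.r1650_1440)
    if est_c < 0:
        notes.append(f"est C=C {est_c:.3g} < 0 clipped to 0")
        est_c = 0.0
    if est_n < 0:
        notes.append(f"est N_C=C/N_CH2 {est_n:.3g} < 0 clipped to 0")
        est_n = 0.0
    try:
        est_mp = _apply(models["mp"], ratios.r1650_1440)
    except RangeError as exc:
        notes.append(f"melting point not invertible: {exc}")
        est_mp = float("nan")
    for n in notes:
        warnings.warn(n, stacklevel=2)
    return LipidQuant(r1650_1440=ratios.r1650_1440,
                      r3003_1440=ratios.r3003_1440,
                      est_c_double_bonds=est_c, est_n_ratio=est_n,
                      est_melting_point=est_mp,
                      excitation_nm=s.excitation_nm, warnings=notes)


def mixture_ratio(components: list[tuple[FattyAcid, float]],
                  coupling: float = 7.3) -> float:
    """Expected I1650/I1440 of a weight-fraction fatty-acid mixture.

    Band areas are mole-additive, so with moles_i proportional to
    w_i / MW_i the expected ratio is
    ``coupling * sum(m_i * N_C=C_i) / sum(m_i * N_CH2_i)`` — always between
    the pure-component ratios.

    Raises
    ------
    ValidationError
        If weights are negative or do not sum to 1 (within 1e-6).
    """
    if not components:
        raise ValidationError("empty mixture")
    w = np.array([wi for _, wi in components], dtype=float)
    if np.any(w < 0):
        raise ValidationError("weight fractions must be >= 0")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"weight fractions must sum to 1 (got {w.sum():.6g})")
    moles = w / np.array([fa.molecular_weight for fa, _ in components])
    num = float(np.dot(moles, [fa.n_double_bonds for fa, _ in components]))
    den = float(np.dot(moles, [fa.n_ch2 for fa, _ in components]))
    if den <= 0:
        raise ValidationError("mixture has no CH2 groups; ratio undefined")
    return coupling * num / den


def double_bonds_from_ratio(ratio: float, n_ch2: float,
                            coupling: float = 7.3) -> float:
    """Exact chain-length-normalized inversion: C=C count from a measured
    ratio for a lipid of known methylene count.

    For a sample of known chain length (e.g. a pure standard) this is the
    preferred inversion — the ratio is linear in N_C=C/N_CH2, not in N_C=C
    across chain lengths.
    """
    if n_ch2 <= 0:
        raise ValidationError("n_ch2 must be positive")
    return ratio * n_ch2 / coupling


def classify_population(quants, thresholds: tuple[float, float] = CLASS_THRESHOLDS
                        ) -> tuple[list[str], Counter]:
    """Label cells by estimated C=C count and histogram the labels.

    ``quants`` is a list of :class:`LipidQuant` or plain estimates; a cell
    is saturated-dominant at or below ``thresholds[0]``, monounsaturated-
    dominant at or above ``thresholds[1]``, mixed in between.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValidationError("thresholds must be increasing")
    values = [q.est_c_double_bonds if isinstance(q, LipidQuant) else float(q)
              for q in quants]
    if not values:
        raise ValidationError("need at least one cell")
    labels = []
    for v in values:
        if v <= lo:
            labels.append(CLASS_LABELS[0])
        elif v >= hi:
            labels.append(CLASS_LABELS[2])
        else:
            labels.append(CLASS_LABELS[1])
    return labels, Counter(labels)


def standard_calibration(excitation_nm: int = 532,
                         registry: list[FattyAcid] | None = None,
                         measured: bool = False, noise_sd: float = 0.0,
                         seed: int = 0) -> dict[str, CalibrationModel]:
    """Build the three calibrations from the synthetic standard panel.

    With ``measured=False`` the standards' ratios are the generator's
    analytic values; with ``measured=True`` each standard is simulated,
    background-subtracted and peak-fitted, so the calibration inherits the
    pipeline's (small) measurement error.
    """
    from .preprocess import subtract_background
    from .synth import analytic_ratio, simulate_standard

    registry = registry or standard_registry()
    ratios = []
    for i, fa in enumerate(registry):
        if measured:
            spec = simulate_standard(fa, excitation_nm, noise_sd,
                                     seed=seed + i)
            flat = subtract_background(spec)
            r = intensity_ratios(flat, noise_sd or None).r1650_1440
        else:
            r = analytic_ratio(fa.n_double_bonds, fa.n_ch2, excitation_nm)
        ratios.append(r)

    c_points = [(r, fa.n_double_bonds) for r, fa in zip(ratios, registry)]
    n_points = [(r, unsaturation_ratio(fa)) if fa.n_ch2 else (r, 0.0)
                for r, fa in zip(ratios, registry)]
    mp_points = [(fa.melting_point, r) for r, fa in zip(ratios, registry)]
    return {
        "c_bonds": fit_linear(c_points, "ratio_1650_1440", "c_double_bonds",
                              excitation_nm),
        "n_ratio": fit_linear(n_points, "ratio_1650_1440", "n_cc_over_n_ch2",
                              excitation_nm),
        "mp": fit_sigmoid_mp(mp_points, excitation_nm, seed=seed),
    }
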