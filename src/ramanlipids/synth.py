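"""Synthetic Raman spectra and hyperspectral scenes.

This module generates every input the rest of the pipeline consumes:
fatty-acid standard spectra, single-cell spectra with pigment and
fluorescence interference, and continuous 2-D scenes with planted lipid
droplets that can be sampled into hypercubes at any window size.

The generator's central contract ties band areas to molecular structure:
the CH2-bend band at 1440 cm-1 carries an area proportional to N_CH2 and
the C=C stretch at 1650 cm-1 an area proportional to kappa * N_C=C, so a
noise-free spectrum has exactly

    I_1650 / I_1440 = kappa * N_C=C / N_CH2

with kappa = 7.3 under 532 nm excitation (anchored so an oleic-like lipid,
N_C=C/N_CH2 = 1/14, gives the reference ratio 0.52) and kappa = 4.2 under
785 nm (so the same lipid gives 0.30, the observed NIR value).  The two
lasers further differ in overall intensity (10x at 532 nm), in the relative
strength of the CH-stretch region (dominant at 532 nm, weak at 785 nm),
and in carotenoid resonance enhancement (boosted at 785 nm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fatty_acids import FattyAcid, parse_fatty_acid
from .hypermap import Hypercube, spot_size
from .spectrum import Spectrum, default_grid

__all__ = [
    "COUPLING", "BLEACH_TAU", "AREA_UNIT", "LIPID_HWHM", "CAROTENOID_HWHM",
    "Band", "CellProfile", "Droplet", "Patch", "Scene",
    "simulate_standard", "simulate_cell", "sample_hypercube",
    "scene_spectrum", "lipid_peak_amplitude", "analytic_ratio",
]

# ---------------------------------------------------------------------------
# Generator constants (all configurable through function arguments).

#: Area coupling of the 1650 cm-1 C=C band per laser:
#: I1650/I1440 = COUPLING[ex] * N_C=C / N_CH2.
COUPLING = {532: 7.3, 785: 4.2}

#: Overall intensity scale per laser (532 nm Raman power ~10x the NIR).
GLOBAL_SCALE = {532: 10.0, 785: 1.0}

#: Relative weight of the CH-stretch region (2800-3100 cm-1): dominant under
#: green excitation, much weaker under NIR.
CH_SCALE = {532: 1.0, 785: 0.08}

#: Carotenoid resonance boost under NIR excitation.
CAROTENOID_SCALE = {532: 1.0, 785: 3.0}

#: Fluorescence background scale per laser (autofluorescence strong at 532).
FLUOR_SCALE = {532: 1.0, 785: 0.05}

#: Photobleach time constant (seconds) for the fluorescence baseline and
#: chlorophyll bands.
BLEACH_TAU = 25.0

#: Resonance-enhanced carotenoid bands photodegrade much faster under the
#: probe laser; after a 30-75 s bleach the 1520 cm-1 band sits far below
#: the lipid analysis bands.
CAROTENOID_BLEACH_TAU = 10.0

#: Base integrated area (counts*cm-1) contributed per CH2 group at unit
#: lipid amount, before the per-laser global scale.
AREA_UNIT = 100.0

LIPID_HWHM = 8.0
CAROTENOID_HWHM = 6.0


@dataclass(frozen=True)
class Band:
    """One Lorentzian component of the spectral model.

    ``source`` names the quantity the band area scales with; ``weight`` is
    the area per unit of that source (in AREA_UNIT units).
    """

    center: float
    hwhm: float
    source: str  # n_ch2 | n_double_bonds | carotenoid | chlorophyll | protein
    weight: float
    ch_region: bool = False  # scaled by the per-laser CH-stretch factor

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValidationError(f"band {self.center}: hwhm must be > 0")
        if self.weight < 0:
            raise ValidationError(f"band {self.center}: weight must be >= 0")


# The C=C stretch (1650 cm-1) is added separately because its weight is the
# per-laser coupling constant.
LIPID_BANDS = (
    Band(1260.0, LIPID_HWHM, "n_double_bonds", 0.40),   # =C-H cis deformation
    Band(1300.0, LIPID_HWHM, "n_ch2", 0.50),            # CH2 twist
    Band(1440.0, LIPID_HWHM, "n_ch2", 1.00),            # CH2 bend (reference)
    Band(2850.0, LIPID_HWHM, "n_ch2", 1.15, ch_region=True),  # CH2 sym stretch
    Band(2885.0, LIPID_HWHM, "n_ch2", 0.95, ch_region=True),  # CH2 asym stretch
    Band(2930.0, LIPID_HWHM, "n_ch2", 0.75, ch_region=True),  # CH3 stretch
    Band(3003.0, LIPID_HWHM, "n_double_bonds", 0.50, ch_region=True),  # =C-H
)

CAROTENOID_BANDS = (
    Band(1006.0, CAROTENOID_HWHM, "carotenoid", 0.60),
    Band(1155.0, CAROTENOID_HWHM, "carotenoid", 0.80),
    Band(1520.0, CAROTENOID_HWHM, "carotenoid", 1.00),
)

CHLOROPHYLL_BANDS = (
    Band(850.0, 12.0, "chlorophyll", 0.25),
    Band(915.0, 12.0, "chlorophyll", 0.25),
    Band(975.0, 12.0, "chlorophyll", 0.25),
    Band(1050.0, 12.0, "chlorophyll", 0.25),
    Band(1110.0, 12.0, "chlorophyll", 0.25),
    Band(1180.0, 12.0, "chlorophyll", 0.25),
)

PROTEIN_BANDS = (
    Band(550.0, LIPID_HWHM, "protein", 0.50),    # disulfide
    Band(1004.0, LIPID_HWHM, "protein", 1.00),   # phenylalanine ring breath
    Band(1245.0, LIPID_HWHM, "protein", 0.70),   # amide III
    Band(1275.0, LIPID_HWHM, "protein", 0.60),   # amide III
    Band(1660.0, 10.0, "protein", 0.80),         # amide I
)


def _check_excitation(excitation_nm: int) -> int:
    ex = int(excitation_nm)
    if ex not in COUPLING:
        raise ValidationError(f"unsupported excitation {excitation_nm} nm")
    return ex


def analytic_ratio(n_double_bonds: float, n_ch2: float,
                   excitation_nm: int = 532) -> float:
    """The generator's exact noise-free I1650/I1440 for a given structure."""
    ex = _check_excitation(excitation_nm)
    if n_ch2 <= 0:
        raise ValidationError("n_ch2 must be positive")
    return COUPLING[ex] * n_double_bonds / n_ch2


def lipid_peak_amplitude(n_ch2: float, excitation_nm: int = 532,
                         amount: float = 1.0) -> float:
    """Peak height (counts) of the 1440 cm-1 band for a given structure."""
    ex = _check_excitation(excitation_nm)
    area = AREA_UNIT * amount * n_ch2 * GLOBAL_SCALE[ex]
    return area / (math.pi * LIPID_HWHM)


# ---------------------------------------------------------------------------
# Mixtures and profiles.

_OLEIC = parse_fatty_acid("C18:1", 13.4)


def _effective_structure(lipids: list[tuple[FattyAcid, float]]) -> tuple[float, float]:
    """Mole-weighted (N_C=C, N_CH2) of a weight-fraction lipid mixture.

    Band areas are additive per mole, so a mixture behaves like a single
    species with mole-averaged double-bond and methylene counts.
    """
    if not lipids:
        raise ValidationError("empty lipid mixture")
    ws = np.array([w for _, w in lipids], dtype=float)
    if np.any(ws < 0):
        raise ValidationError("lipid weight fractions must be >= 0")
    if ws.sum() <= 0:
        raise ValidationError("lipid weight fractions sum to zero")
    moles = ws / np.array([fa.molecular_weight for fa, _ in lipids])
    moles /= moles.sum()
    n_db = float(np.dot(moles, [fa.n_double_bonds for fa, _ in lipids]))
    n_ch2 = float(np.dot(moles, [fa.n_ch2 for fa, _ in lipids]))
    return n_db, n_ch2


@dataclass
class CellProfile:
    """Composition of a simulated algal cell.

    ``lipids`` are (fatty acid, weight fraction) pairs; pigment and protein
    weights are in AREA_UNIT area units; ``fluorescence`` is the unbleached
    baseline amplitude in counts (532 nm scale).
    """

    lipids: list[tuple[FattyAcid, float]] = field(
        default_factory=lambda: [(_OLEIC, 1.0)])
    lipid_amount: float = 1.0
    carotenoid: float = 8.0
    chlorophyll: float = 6.0
    protein: float = 0.0
    fluorescence: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("lipid_amount", "carotenoid", "chlorophyll", "protein",
                     "fluorescence"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        # validates lipid weights too
        self._n_db, self._n_ch2 = _effective_structure(self.lipids)

    @classmethod
    def cc503_like(cls) -> "CellProfile":
        """Reference profile: oleic-dominant lipid with default pigments,
        emulating the C. reinhardtii CC-503 benchmark."""
        return cls()

    @property
    def effective_n_double_bonds(self) -> float:
        return self._n_db

    @property
    def effective_n_ch2(self) -> float:
        return self._n_ch2


# ---------------------------------------------------------------------------
# Core synthesis.

def _unit_lorentzians(grid: np.ndarray, bands, ex: int) -> tuple[np.ndarray, list]:
    """Unit-area Lorentzian profiles (n_bands, n_w) for bands inside the grid."""
    kept = [b for b in bands if grid[0] <= b.center <= grid[-1]]
    prof = np.empty((len(kept), grid.size))
    for i, b in enumerate(kept):
        prof[i] = (b.hwhm / math.pi) / ((grid - b.center) ** 2 + b.hwhm ** 2)
    return prof, kept


def _synthesize(grid: np.ndarray, excitation_nm: int,
                n_db, n_ch2, carotenoid, chlorophyll, protein,
                fluorescence, bleach_seconds: float = 0.0,
                coupling: dict | None = None,
                bleach_tau: float = BLEACH_TAU) -> np.ndarray:
    """Noise-free intensity matrix for scalar or per-pixel composition arrays.

    All composition arguments broadcast to a common shape ``(n,)``; returns
    ``(n, n_w)`` (squeezed to ``(n_w,)`` for scalar input).
    """
    ex = _check_excitation(excitation_nm)
    kappa = (coupling or COUPLING)[ex]
    n_db, n_ch2, carotenoid, chlorophyll, protein, fluorescence = [
        np.atleast_1d(np.asarray(a, dtype=float))
        for a in (n_db, n_ch2, carotenoid, chlorophyll, protein, fluorescence)]
    scalar = n_db.size == 1 and carotenoid.size == 1
    n = max(a.size for a in (n_db, n_ch2, carotenoid, chlorophyll, protein,
                             fluorescence))
    decay = math.exp(-bleach_seconds / bleach_tau) if bleach_seconds > 0 else 1.0
    car_decay = (math.exp(-bleach_seconds / CAROTENOID_BLEACH_TAU)
                 if bleach_seconds > 0 else 1.0)

    bands = list(LIPID_BANDS) + [Band(1650.0, LIPID_HWHM, "n_double_bonds", kappa)] \
        + list(CAROTENOID_BANDS) + list(CHLOROPHYLL_BANDS) + list(PROTEIN_BANDS)
    prof, kept = _unit_lorentzians(grid, bands, ex)

    g = GLOBAL_SCALE[ex]
    sources = {
        "n_ch2": np.broadcast_to(n_ch2, (n,)),
        "n_double_bonds": np.broadcast_to(n_db, (n,)),
        "carotenoid": np.broadcast_to(carotenoid, (n,)) * car_decay
        * CAROTENOID_SCALE[ex],
        "chlorophyll": np.broadcast_to(chlorophyll, (n,)) * decay,
        "protein": np.broadcast_to(protein, (n,)),
    }
    areas = np.zeros((n, len(kept)))
    for i, b in enumerate(kept):
        a = AREA_UNIT * b.weight * sources[b.source] * g
        if b.ch_region:
            a = a * CH_SCALE[ex]
        areas[:, i] = a
    y = areas @ prof

    fl = np.broadcast_to(fluorescence, (n,))[:, None] * decay * FLUOR_SCALE[ex]
    baseline = 0.8 * np.exp(-grid / 1200.0) + 0.2
    y = y + fl * baseline[None, :]
    return y[0] if scalar else y


def simulate_standard(fa: FattyAcid, excitation_nm: int = 532,
                      noise_sd: float = 0.0, seed: int = 0, *,
                      amount: float = 1.0, accumulations: int = 1,
                      coupling: dict | None = None) -> Spectrum:
    """Spectrum of a pure fatty-acid standard on the default grid.

    Band areas follow the generator contract: area(1440) proportional to
    N_CH2, area(1650) = kappa * N_C=C in the same units, so the noise-free
    area ratio is exactly ``analytic_ratio(fa)``.  Additive Gaussian noise
    of standard deviation ``noise_sd`` counts per accumulation; averaging
    ``accumulations`` acquisitions divides the effective noise by its
    square root.  Deterministic under ``seed``.
    """
    ex = _check_excitation(excitation_nm)
    grid = default_grid()
    y = _synthesize(grid, ex, fa.n_double_bonds * amount, fa.n_ch2 * amount,
                    0.0, 0.0, 0.0, 0.0, coupling=coupling)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if accumulations < 1:
        raise ValidationError("accumulations must be >= 1")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd / math.sqrt(accumulations),
                           size=y.shape)
    meta = {"kind": "standard", "fatty_acid": fa.code, "seed": str(seed),
            "noise_sd": f"{noise_sd:g}", "excitation_nm": str(ex)}
    return Spectrum(grid, y, ex, meta)


def simulate_cell(profile: CellProfile | None = None,
                  bleach_seconds: float = 75.0, excitation_nm: int = 532,
                  noise_sd: float | None = None, seed: int = 0, *,
                  accumulations: int = 10,
                  coupling: dict | None = None,
                  bleach_tau: float = BLEACH_TAU) -> Spectrum:
    """Single-cell spectrum: lipid bands plus carotenoid, chlorophyll and
    optional protein bands, on a fluorescence baseline.

    Pigment bands and the fluorescence baseline decay as
    ``exp(-bleach_seconds / bleach_tau)``, emulating controlled
    photobleaching; protein and lipid bands do not bleach.  The default
    per-accumulation noise is 2 % of the profile's CH2-bend peak height;
    single-cell acquisitions average ``accumulations`` (default 10)
    exposures, dividing the effective noise by its square root.
    """
    ex = _check_excitation(excitation_nm)
    if bleach_seconds < 0:
        raise ValidationError("bleach_seconds must be >= 0")
    if accumulations < 1:
        raise ValidationError("accumulations must be >= 1")
    profile = profile or CellProfile.cc503_like()
    if noise_sd is None:
        noise_sd = 0.02 * lipid_peak_amplitude(
            profile.effective_n_ch2, ex, profile.lipid_amount)
    grid = default_grid()
    a = profile.lipid_amount
    y = _synthesize(grid, ex,
                    profile.effective_n_double_bonds * a,
                    profile.effective_n_ch2 * a,
                    profile.carotenoid, profile.chlorophyll, profile.protein,
                    profile.fluorescence, bleach_seconds,
                    coupling=coupling, bleach_tau=bleach_tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd / math.sqrt(accumulations),
                           size=y.shape)
    meta = {"kind": "cell", "bleach_seconds": f"{bleach_seconds:g}",
            "seed": str(seed), "noise_sd": f"{noise_sd:g}",
            "excitation_nm": str(ex)}
    return Spectrum(grid, y, ex, meta)


# ---------------------------------------------------------------------------
# Scenes and hypercube sampling.

@dataclass
class Droplet:
    """A circular lipid body planted in a scene."""

    x: float
    y: float
    radius: float
    lipids: list[tuple[FattyAcid, float]] = field(
        default_factory=lambda: [(_OLEIC, 1.0)])
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("droplet radius must be > 0")
        if self.concentration < 0:
            raise ValidationError("droplet concentration must be >= 0")
        self._n_db, self._n_ch2 = _effective_structure(self.lipids)


@dataclass
class Patch:
    """A circular region of extra pigment/protein background."""

    x: float
    y: float
    radius: float
    carotenoid: float = 0.0
    chlorophyll: float = 0.0
    protein: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("patch radius must be > 0")
        for name in ("carotenoid", "chlorophyll", "protein"):
            if getattr(self, name) < 0:
                raise ValidationError(f"patch {name} must be >= 0")


@dataclass
class Scene:
    """A continuous 2-D sample: droplets and pigment patches on a uniform
    background, over a rectangular extent in micrometres (origin lower-left,
    x right, y up)."""

    extent: tuple[float, float]
    droplets: list[Droplet] = field(default_factory=list)
    patches: list[Patch] = field(default_factory=list)
    background_carotenoid: float = 0.0
    background_chlorophyll: float = 0.0
    background_protein: float = 0.0
    background_lipid: float = 0.0
    fluorescence: float = 0.0

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValidationError("scene extent must be positive")
        for d in self.droplets:
            if not (0 <= d.x <= w and 0 <= d.y <= h):
                raise ValidationError(
                    f"droplet at ({d.x}, {d.y}) outside scene extent {self.extent}")
        for name in ("background_carotenoid", "background_chlorophyll",
                     "background_protein", "background_lipid", "fluorescence"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# disk quadrature resolution for PSF-droplet overlap integrals
_QUAD_NR, _QUAD_NT = 6, 12


def _disk_overlap(px: np.ndarray, py: np.ndarray, cx: float, cy: float,
                  radius: float, sigma: float) -> np.ndarray:
    """Fraction of a Gaussian PSF centred at each (px, py) falling inside the
    disk of given centre and radius (polar quadrature; smooth and monotone
    in the centre distance)."""
    rj = radius * np.sqrt((np.arange(_QUAD_NR) + 0.5) / _QUAD_NR)
    tk = 2.0 * math.pi * (np.arange(_QUAD_NT) + 0.5) / _QUAD_NT
    qx = cx + np.outer(rj, np.cos(tk)).ravel()
    qy = cy + np.outer(rj, np.sin(tk)).ravel()
    cell_area = math.pi * radius ** 2 / (_QUAD_NR * _QUAD_NT)
    d2 = (px[:, None] - qx[None, :]) ** 2 + (py[:, None] - qy[None, :]) ** 2
    psf = np.exp(-d2 / (2.0 * sigma ** 2)) / (2.0 * math.pi * sigma ** 2)
    return psf.sum(axis=1) * cell_area


def _composition_at(scene: Scene, px: np.ndarray, py: np.ndarray,
                    excitation_nm: int, numerical_aperture: float):
    """Per-point effective lipid (N_C=C, N_CH2) amounts and pigment weights,
    integrating the scene over the excitation's diffraction-limited spot."""
    sigma = spot_size(excitation_nm, numerical_aperture) / 2.3548  # FWHM -> sd
    n = px.size
    m_db = np.full(n, 0.0)
    m_ch2 = np.full(n, 0.0)
    if scene.background_lipid > 0:
        m_db += scene.background_lipid * _OLEIC.n_double_bonds
        m_ch2 += scene.background_lipid * _OLEIC.n_ch2
    for d in scene.droplets:
        ov = _disk_overlap(px, py, d.x, d.y, d.radius, sigma) * d.concentration
        m_db += ov * d._n_db
        m_ch2 += ov * d._n_ch2
    car = np.full(n, float(scene.background_carotenoid))
    chl = np.full(n, float(scene.background_chlorophyll))
    prot = np.full(n, float(scene.background_protein))
    for p in scene.patches:
        ov = _disk_overlap(px, py, p.x, p.y, p.radius, sigma)
        car += ov * p.carotenoid
        chl += ov * p.chlorophyll
        prot += ov * p.protein
    return m_db, m_ch2, car, chl, prot


def scene_spectrum(scene: Scene, point: tuple[float, float],
                   excitation_nm: int = 532, noise_sd: float = 0.0,
                   seed: int = 0, numerical_aperture: float = 0.8) -> Spectrum:
    """The single spectrum the instrument would record at one point."""
    ex = _check_excitation(excitation_nm)
    grid = default_grid()
    px = np.array([point[0]], float)
    py = np.array([point[1]], float)
    m_db, m_ch2, car, chl, prot = _composition_at(scene, px, py, ex,
                                                  numerical_aperture)
    y = _synthesize(grid, ex, m_db, m_ch2, car, chl, prot,
                    scene.fluorescence)
    if y.ndim == 2:
        y = y[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    meta = {"kind": "scene-point", "x_um": f"{point[0]:g}",
            "y_um": f"{point[1]:g}", "seed": str(seed),
            "excitation_nm": str(ex)}
    return Spectrum(grid, y, ex, meta)


def sample_hypercube(scene: Scene, center: tuple[float, float], window: float,
                     n: int = 10, excitation_nm: int = 532, seed: int = 0,
                     noise_sd: float = 0.0,
                     numerical_aperture: float = 0.8) -> Hypercube:
    """Sample an n x n hyperspectral map of a square window of the scene.

    Pixel centres follow the half-open window convention
    ``[c - w/2, c + w/2)``; each pixel integrates the continuous scene over
    the excitation's diffraction-limited Gaussian spot.  Windows extending
    beyond the scene are shifted inside with a warning.  Repeatable under a
    fixed seed; the same scene can be re-sampled at any finer window.
    """
    ex = _check_excitation(excitation_nm)
    if window <= 0:
        raise ValidationError("window must be > 0")
    if n < 2:
        raise ValidationError("need at least 2 pixels per side")
    w_ext, h_ext = scene.extent
    if window > w_ext or window > h_ext:
        raise ValidationError(
            f"window {window} um exceeds scene extent {scene.extent}")
    ox, oy = center[0] - window / 2.0, center[1] - window / 2.0
    cox = min(max(ox, 0.0), w_ext - window)
    coy = min(max(oy, 0.0), h_ext - window)
    if (cox, coy) != (ox, oy):
        warnings.warn("sampling window clipped to scene extent", stacklevel=2)
        ox, oy = cox, coy

    step = window / n
    xs = ox + (np.arange(n) + 0.5) * step
    ys = oy + (np.arange(n) + 0.5) * step
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    px, py = gx.ravel(), gy.ravel()

    grid = default_grid()
    m_db, m_ch2, car, chl, prot = _composition_at(scene, px, py, ex,
                                                  numerical_aperture)
    y = _synthesize(grid, ex, m_db, m_ch2, car, chl, prot, scene.fluorescence)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    cube = y.reshape(n, n, grid.size)
    meta = {"seed": str(seed), "noise_sd": f"{noise_sd:g}",
            "window_um": f"{window:g}"}
    return Hypercube(intensities=cube, wavenumbers=grid, excitation_nm=ex,
                     step=step, origin=(ox, oy), meta=meta)
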