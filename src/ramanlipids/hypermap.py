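"""Hyperspectral image analysis and diffraction-optics helpers.

Band-integral chemical maps (protein / carotenoid / lipid component
images), the coarse-to-fine lipid-body localization loop (sample a low
pixel-density map, re-centre on the brightest lipid pixel, halve the
window, repeat down to ~1x1 um^2), best-spectrum extraction, and the
Airy-disk spot size / lateral resolution closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LocalizationError, ValidationError
from .preprocess import DEFAULT_BACKGROUND_WINDOW, moving_average_matrix
from .spectrum import Spectrum

__all__ = [
    "Hypercube", "BandImage", "ComponentMaps", "band_image", "component_maps",
    "locate_lipid_region", "LocateResult", "spot_size", "lateral_resolution",
    "default_lipid_band", "COMPONENT_BANDS",
]

#: Component image bands: phenylalanine ring breathing (protein), the
#: dominant carotenoid resonance band, the CH2 bend (lipid bodies).
COMPONENT_BANDS = {
    "protein": (995.0, 1012.0),
    "carotenoid": (1505.0, 1535.0),
    "lipid": (1380.0, 1500.0),
}

_COMPOSITE_LABELS = {0: "none", 1: "protein", 2: "carotenoid", 3: "lipid"}


# ---------------------------------------------------------------------------
# Optics.

def _check_optics(excitation_nm: float, numerical_aperture: float) -> None:
    if excitation_nm <= 0:
        raise ValidationError("excitation wavelength must be positive")
    if not 0 < numerical_aperture <= 1.5:
        raise ValidationError("numerical aperture must be in (0, 1.5]")


def spot_size(excitation_nm: float, numerical_aperture: float = 0.8) -> float:
    """Airy-disk laser spot diameter 1.22*lambda/NA in micrometres."""
    _check_optics(excitation_nm, numerical_aperture)
    return 1.22 * (excitation_nm / 1000.0) / numerical_aperture


def lateral_resolution(excitation_nm: float,
                       numerical_aperture: float = 0.8) -> float:
    """Diffraction-limited lateral resolution 0.42*lambda/NA in micrometres."""
    _check_optics(excitation_nm, numerical_aperture)
    return 0.42 * (excitation_nm / 1000.0) / numerical_aperture


def default_lipid_band(excitation_nm: int) -> tuple[float, float]:
    """The most intense lipid band for localization: the CH-stretch envelope
    under green excitation, the CH2 bend under NIR."""
    return (2800.0, 3000.0) if int(excitation_nm) == 532 else (1380.0, 1500.0)


# ---------------------------------------------------------------------------
# Containers.

@dataclass
class Hypercube:
    """An nx x ny grid of spectra over a physical scan window.

    ``intensities`` has shape (ny, nx, n_wavenumbers); all pixels share one
    wavenumber axis.  ``origin`` is the lower-left corner of the sampled
    window in scene coordinates (um, x right / y up); ``step`` the pixel
    pitch in um.
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    excitation_nm: int
    step: float
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be (ny, nx, n_wavenumbers)")
        ny, nx, nw = self.intensities.shape
        if nx * ny < 4:
            raise ValidationError("hypercube needs at least 4 pixels")
        if nw != self.wavenumbers.size:
            raise ValidationError("pixel spectra do not match wavenumber axis")
        if self.step <= 0:
            raise ValidationError("pixel step must be > 0")

    @property
    def ny(self) -> int:
        return self.intensities.shape[0]

    @property
    def nx(self) -> int:
        return self.intensities.shape[1]

    def spectrum(self, ix: int, iy: int) -> Spectrum:
        """The spectrum at pixel column ix, row iy."""
        return Spectrum(self.wavenumbers.copy(),
                        self.intensities[iy, ix].copy(),
                        self.excitation_nm,
                        {"pixel": f"{ix},{iy}", **self.meta})

    def pixel_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (self.origin[0] + (ix + 0.5) * self.step,
                self.origin[1] + (iy + 0.5) * self.step)


@dataclass
class BandImage:
    """Per-pixel integrated intensity over a wavenumber band."""

    values: np.ndarray
    band: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("band image values must be finite")

    def argmax_pixel(self) -> tuple[int, int]:
        """(ix, iy) of the maximum; ties break at the lowest (row, column)
        index, deterministically."""
        iy, ix = np.unravel_index(int(np.argmax(self.values)),
                                  self.values.shape)
        return int(ix), int(iy)

    def to_text(self) -> str:
        header = (f"# band_lo_cm1: {self.band[0]:g}\n"
                  f"# band_hi_cm1: {self.band[1]:g}\n"
                  f"# label: {self.label}\n")
        body = "\n".join("\t".join(f"{v:.12g}" for v in row)
                         for row in self.values)
        return header + body + "\n"


# ---------------------------------------------------------------------------
# Chemical maps.

def band_image(h: Hypercube, band: tuple[float, float],
               label: str = "",
               background_window_cm1: float = DEFAULT_BACKGROUND_WINDOW
               ) -> BandImage:
    """Background-subtracted band integral per pixel.

    Each pixel spectrum has the moving-average background removed, then is
    integrated (trapezoid) over ``band``.
    """
    lo, hi = band
    w = h.wavenumbers
    if lo >= hi or lo < w[0] or hi > w[-1]:
        raise ValidationError(f"band ({lo}, {hi}) outside grid")
    step = float(w[1] - w[0])
    flat = h.intensities.reshape(-1, w.size)
    flat = flat - moving_average_matrix(flat, step, background_window_cm1)
    i0 = int(np.searchsorted(w, lo, side="left"))
    i1 = int(np.searchsorted(w, hi, side="right"))
    vals = np.trapezoid(flat[:, i0:i1], w[i0:i1], axis=1)
    return BandImage(vals.reshape(h.ny, h.nx), (lo, hi), label)


@dataclass
class ComponentMaps:
    """Protein / carotenoid / lipid band images plus a composite label map
    (0 none, 1 protein, 2 carotenoid, 3 lipid)."""

    protein: BandImage
    carotenoid: BandImage
    lipid: BandImage
    labels: np.ndarray

    LABELS = _COMPOSITE_LABELS


def _channel_floor(values: np.ndarray) -> float:
    """Noise floor of one component image: median + 5 * robust sigma."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + 5.0 * 1.4826 * mad


def component_maps(h: Hypercube) -> ComponentMaps:
    """Chemical component images and the composite assignment.

    Each channel is zeroed below its own noise floor, normalized to its
    maximum, and every pixel takes the label of its largest normalized
    component (0 where no channel survives the floor).  Normalization makes
    the composite invariant to global intensity rescaling.
    """
    images = {k: band_image(h, b, k) for k, b in COMPONENT_BANDS.items()}
    stack = []
    for k in ("protein", "carotenoid", "lipid"):
        v = images[k].values.copy()
        floor = _channel_floor(v)
        v[v <= max(floor, 0.0)] = 0.0
        vmax = v.max()
        stack.append(v / vmax if vmax > 0 else v)
    stack = np.stack(stack)  # (3, ny, nx)
    labels = np.argmax(stack, axis=0) + 1
    labels[np.all(stack <= 0, axis=0)] = 0
    return ComponentMaps(protein=images["protein"],
                         carotenoid=images["carotenoid"],
                         lipid=images["lipid"], labels=labels)


# ---------------------------------------------------------------------------
# Coarse-to-fine localization.

@dataclass
class LocateResult:
    """Outcome of the iterative lipid-body search."""

    center: tuple[float, float]
    spectrum: Spectrum
    trace: list[tuple[int, tuple[float, float], float]]  # (iter, center, window)
    n_iterations: int


def locate_lipid_region(scene, start_center: tuple[float, float],
                        start_window: float, n: int = 10,
                        excitation_nm: int = 532, stop_window: float = 1.0,
                        seed: int = 0, noise_sd: float = 0.0,
                        band: tuple[float, float] | None = None,
                        numerical_aperture: float = 0.8) -> LocateResult:
    """Find the strongest lipid body by iterative area reduction.

    Each iteration samples an n x n map (10 x 10 by default) of the current
    window, integrates the excitation's default lipid band, re-centres on
    the brightest pixel and halves the window; the loop runs while the
    window exceeds ``stop_window`` (~1x1 um^2), i.e. exactly
    ``ceil(log2(start_window / stop_window))`` iterations.  The single best
    spectrum is then extracted at the final centre.

    Raises
    ------
    LocalizationError
        When the first map has no pixel above the noise floor (e.g. a
        uniform scene: the maximum does not stand out of the image spread).
    """
    from .synth import sample_hypercube, scene_spectrum  # lazy: module cycle
    if start_window <= stop_window:
        raise ValidationError("start_window must exceed stop_window")
    if n < 2:
        raise ValidationError("need at least 2 pixels per side")
    band = band or default_lipid_band(excitation_nm)

    center = tuple(start_center)
    window = float(start_window)
    trace: list[tuple[int, tuple[float, float], float]] = []
    iteration = 0
    while window > stop_window:
        iteration += 1
        cube = sample_hypercube(scene, center, window, n, excitation_nm,
                                seed=seed + iteration, noise_sd=noise_sd,
                                numerical_aperture=numerical_aperture)
        img = band_image(cube, band, "lipid")
        if iteration == 1:
            v = img.values
            med = float(np.median(v))
            sigma = 1.4826 * float(np.median(np.abs(v - med)))
            if float(v.max()) <= med + 5.0 * sigma:
                raise LocalizationError(
                    "no pixel above the noise floor in the first map; "
                    "nothing to localize")
        ix, iy = img.argmax_pixel()
        center = cube.pixel_center(ix, iy)
        trace.append((iteration, center, window))
        window /= 2.0

    best = scene_spectrum(scene, center, excitation_nm, noise_sd,
                          seed=seed + iteration + 1,
                          numerical_aperture=numerical_aperture)
    return LocateResult(center=center, spectrum=best, trace=trace,
                        n_iterations=iteration)
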