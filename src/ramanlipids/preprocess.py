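"""Background subtraction and spectral quality control.

Acquisition hygiene for the ratiometric method: a moving-average background
subtraction (the same filter applied to standards and unknowns), a protein
contamination screen on the amide III / disulfide / phenylalanine marker
windows, and a photobleach adequacy check comparing the dominant carotenoid
band (1520 cm-1) to the lipid analysis bands (1440 and 1650 cm-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import QCError, ValidationError, FitError
from .spectrum import Spectrum

__all__ = [
    "QCReport", "subtract_background", "protein_screen", "photobleach_check",
    "qc_report", "estimate_noise_sd",
    "DEFAULT_BACKGROUND_WINDOW", "PROTEIN_SCREEN_WINDOWS",
    "PROTEIN_THRESHOLD_SIGMA", "PHOTOBLEACH_MAX_RATIO",
]

#: Moving-average window in cm-1 (held constant across standards and samples).
DEFAULT_BACKGROUND_WINDOW = 300.0

#: Marker windows screened for protein contamination: disulfide stretch,
#: aromatic (phenylalanine) ring breathing, amide III.
PROTEIN_SCREEN_WINDOWS = ((540.0, 560.0), (999.0, 1009.0), (1220.0, 1300.0))

#: A screened window flags contamination when its fitted peak height exceeds
#: this many noise standard deviations.
PROTEIN_THRESHOLD_SIGMA = 5.0

#: Photobleach passes when area(1520) / min(area(1440), area(1650)) is below
#: this ("far below the lipid analysis peaks").
PHOTOBLEACH_MAX_RATIO = 0.5

#: Signal-free region used for noise estimation.
_SILENT_REGION = (1800.0, 2600.0)


@dataclass
class QCReport:
    """Outcome of the spectral quality screens."""

    protein_contaminated: bool
    offending_bands: list[float]
    photobleach_ok: bool
    carotenoid_to_lipid: float
    snr: float
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if bool(self.offending_bands) != self.protein_contaminated:
            raise ValidationError(
                "offending band list must be non-empty iff contaminated")
        if self.carotenoid_to_lipid < 0:
            raise ValidationError("carotenoid_to_lipid must be >= 0")

    @property
    def passed(self) -> bool:
        return (not self.protein_contaminated) and self.photobleach_ok

    def to_text(self) -> str:
        lines = [
            f"protein_contaminated: {self.protein_contaminated}",
            f"offending_bands: {','.join(f'{b:g}' for b in self.offending_bands)}",
            f"photobleach_ok: {self.photobleach_ok}",
            f"carotenoid_to_lipid: {self.carotenoid_to_lipid:g}",
            f"snr: {self.snr:g}",
        ]
        for r in self.reasons:
            lines.append(f"reason: {r}")
        return "\n".join(lines) + "\n"


def subtract_background(s: Spectrum,
                        window_cm1: float = DEFAULT_BACKGROUND_WINDOW) -> Spectrum:
    """Remove a centred moving-average of the spectrum from itself.

    Reflect padding at the edges; the output grid is identical.  By contract
    the same ``window_cm1`` must be applied to calibration standards and
    unknowns, so residual peak distortion is constant across samples.
    """
    step = s.step
    span = s.wavenumbers[-1] - s.wavenumbers[0]
    if window_cm1 < 3 * step:
        raise ValidationError(
            f"background window {window_cm1} cm-1 below 3x grid step {step}")
    if window_cm1 > span:
        raise ValidationError(
            f"background window {window_cm1} cm-1 exceeds spectral range {span}")
    size = int(round(window_cm1 / step))
    if size % 2 == 0:
        size += 1
    bg = uniform_filter1d(s.intensities, size=size, mode="reflect")
    return s.copy_with(s.intensities - bg,
                       background_window_cm1=f"{window_cm1:g}")


def moving_average_matrix(intensities: np.ndarray, step: float,
                          window_cm1: float = DEFAULT_BACKGROUND_WINDOW) -> np.ndarray:
    """Row-wise moving average for stacked spectra (used on hypercubes)."""
    size = int(round(window_cm1 / step))
    if size % 2 == 0:
        size += 1
    return uniform_filter1d(intensities, size=size, axis=-1, mode="reflect")


def estimate_noise_sd(s: Spectrum) -> float:
    """Robust noise estimate from the signal-free 1800-2600 cm-1 region
    of a background-subtracted spectrum (1.4826 * MAD)."""
    sl = s.window_slice(*_SILENT_REGION)
    seg = s.intensities[sl]
    return float(1.4826 * np.median(np.abs(seg - np.median(seg))))


def _band_area(s: Spectrum, window: tuple[float, float], center: float,
               noise_sd: float = 0.0, seed: int = 0) -> float:
    """Fitted Lorentzian area in a window; 0 for an empty or undetectable
    band (same detection gate as the ratio fits)."""
    from .peakfit import _area_or_zero  # local import to avoid a module cycle
    return _area_or_zero(s, window, (center,), center, noise_sd, seed)


#: Sub-windows inside the protein screen that belong to genuine lipid bands
#: (=C-H cis deformation at 1260 cm-1; CH2 twist flank near 1300 cm-1):
#: peaks centred there never count as protein.
LIPID_EXCLUSION_ZONES = ((1252.0, 1268.0), (1290.0, 1310.0))


def protein_screen(s: Spectrum, noise_sd: float | None = None) -> QCReport:
    """Screen a background-subtracted spectrum for protein bands.

    Candidate peaks in each marker window are local maxima with prominence
    above ``PROTEIN_THRESHOLD_SIGMA * noise_sd``; each candidate is refined
    by a single-Lorentzian fit and flags the spectrum when its fitted height
    exceeds the same threshold.  Peaks inside the lipid exclusion zones
    (the unsaturation band at 1260 cm-1, the CH2-twist flank near 1300 cm-1)
    are ignored.  The amide I overlap at 1650 cm-1 is deliberately not
    screened: the amide III / 550 / 1004 markers decide contamination.
    """
    from scipy.signal import find_peaks

    from .peakfit import fit_window
    if noise_sd is None:
        noise_sd = estimate_noise_sd(s)
    # the moving-average filter leaves residual distortion of order 0.1 % of
    # the reference band even on noise-free data; the detection floor sits
    # above it (and keeps the screen scale-invariant)
    ref = float(np.max(s.intensities[s.window_slice(1380.0, 1500.0)]))
    floor = 1e-3 * max(ref, float(np.max(np.abs(s.intensities))) * 1e-3)
    threshold = PROTEIN_THRESHOLD_SIGMA * max(noise_sd, floor, 1e-12)

    def excluded(center: float) -> bool:
        return any(zlo <= center <= zhi for zlo, zhi in LIPID_EXCLUSION_ZONES)

    def carotenoid_explains(center: float, amp: float) -> bool:
        """The carotenoid 1006 cm-1 band overlaps the phenylalanine marker;
        a residual peak there is attributed to carotenoid when the partner
        carotenoid band at 1155 cm-1 (no protein band nearby) is present
        at comparable height."""
        if not 999.0 <= center <= 1012.0:
            return False
        seg = s.intensities[s.window_slice(1145.0, 1165.0)]
        return float(np.max(seg)) > 0.5 * amp

    offending: list[float] = []
    for lo, hi in PROTEIN_SCREEN_WINDOWS:
        # pad the candidate search so prominence is judged against the local
        # baseline, not the window edges (the 1004 window is only 10 cm-1)
        sl = s.window_slice(lo - 15.0, hi + 15.0)
        seg = s.intensities[sl]
        wseg = s.wavenumbers[sl]
        idx, _ = find_peaks(seg, prominence=threshold)
        for i in idx:
            center, amp = float(wseg[i]), float(seg[i])
            raw_amp = amp
            if not (lo - 2.0 <= center <= hi + 2.0) or excluded(center):
                continue
            try:
                res = fit_window(s, (max(lo, center - 20.0), min(hi, center + 20.0)),
                                 n_components=1, init_centers=[center])
                center, amp = res.peaks[0].center, res.peaks[0].amplitude
            except FitError:
                pass
            if excluded(center) or carotenoid_explains(center, raw_amp):
                continue
            if amp > threshold:
                offending.append(round(center, 1))
    offending = sorted(set(offending))
    snr = _snr(s, max(noise_sd, 1e-12))
    return QCReport(protein_contaminated=bool(offending),
                    offending_bands=offending,
                    photobleach_ok=True, carotenoid_to_lipid=0.0, snr=snr,
                    reasons=[f"protein band near {b} cm-1" for b in offending])


def _snr(s: Spectrum, noise_sd: float) -> float:
    sl = s.window_slice(1380.0, 1500.0)
    peak = float(np.max(s.intensities[sl]))
    return peak / noise_sd if noise_sd > 0 else float("inf")


def photobleach_check(s: Spectrum,
                      noise_sd: float | None = None) -> tuple[bool, float, list[str]]:
    """Check that the dominant carotenoid band is far below the lipid bands.

    Computes ``area(1520) / min(area(1440), area(1650))`` on a
    background-subtracted spectrum; passes iff the ratio is below
    ``PHOTOBLEACH_MAX_RATIO``.  A band below the detection limit counts as
    area zero.  Returns (ok, ratio, reasons).
    """
    if noise_sd is None:
        noise_sd = estimate_noise_sd(s)
    a1440 = _band_area(s, (1380.0, 1500.0), 1440.0, noise_sd)
    if a1440 <= 0:
        return False, float("inf"), ["1440 cm-1 band absent; check undefined"]
    a1650 = _band_area(s, (1600.0, 1700.0), 1650.0, noise_sd)
    # wide window: the narrow carotenoid band sits on the residual dip left
    # between the two strong lipid bands by the moving-average filter
    a1520 = _band_area(s, (1490.0, 1560.0), 1520.0, noise_sd)
    denom = min(a1440, a1650)
    if denom <= 0:
        return False, float("inf"), [
            "1650 cm-1 band absent; carotenoid comparison undefined"]
    ratio = a1520 / denom
    ok = ratio < PHOTOBLEACH_MAX_RATIO
    reasons = [] if ok else [
        f"carotenoid 1520 band at {ratio:.2f}x the weakest lipid band "
        f"(limit {PHOTOBLEACH_MAX_RATIO})"]
    return ok, ratio, reasons


def qc_report(s: Spectrum, background_window_cm1: float = DEFAULT_BACKGROUND_WINDOW,
              noise_sd: float | None = None, *,
              already_subtracted: bool = False) -> QCReport:
    """Full QC: background subtraction, protein screen, photobleach check."""
    flat = s if already_subtracted else subtract_background(s, background_window_cm1)
    rep = protein_screen(flat, noise_sd)
    ok, ratio, reasons = photobleach_check(flat, noise_sd)
    rep.photobleach_ok = ok
    rep.carotenoid_to_lipid = ratio if np.isfinite(ratio) else ratio
    rep.reasons.extend(reasons)
    return rep


def require_clean(s: Spectrum, noise_sd: float | None = None) -> None:
    """Raise :class:`QCError` if a background-subtracted spectrum is
    protein-contaminated."""
    rep = protein_screen(s, noise_sd)
    if rep.protein_contaminated:
        raise QCError("spectrum fails protein screen: "
                      + "; ".join(rep.reasons))
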