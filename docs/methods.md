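# Methods

## Spectral model

Every synthetic spectrum lives on the acquisition grid 0–3400 cm⁻¹ at
3 cm⁻¹ resolution (1134 points) and is a sum of Lorentzian components
`A / (1 + ((ν − ν₀)/γ)²)` plus, for cells, a fluorescence baseline and
additive Gaussian detector noise.  Lorentzians are the natural
condensed-phase lineshape here and their integral has the closed form
π·A·γ used throughout as the "integrated intensity" I_ν.

Lipid bands (HWHM 8 cm⁻¹) scale with the molecular structure of the
(mixture-averaged) fatty acid: the CH₂ twist (1300), CH₂ bend (1440) and
CH-stretch envelope (2850/2885/2930) scale with the methylene count
N_CH₂; the =C–H cis deformation (1260), C=C stretch (1650) and olefinic
=C–H stretch (3003) scale with the double-bond count N_C=C.  The
olefinic stretch is placed at 3003 cm⁻¹ (values between 3003 and
3023 cm⁻¹ appear in the literature; both lie inside the fitted
2800–3100 cm⁻¹ window).

The central generator contract fixes the area coupling of the C=C band so
that, noise-free,

    I₁₆₅₀ / I₁₄₄₀ = κ · N_C=C / N_CH₂ ,   κ₅₃₂ = 7.3,  κ₇₈₅ = 4.2.

κ₅₃₂ is anchored so an oleic-like lipid (N_C=C/N_CH₂ = 1/14) yields the
532 nm benchmark ratio 0.52; κ₇₈₅ is anchored the same way to the 785 nm
benchmark 0.30 for the same lipid.  Both are configurable.

Two-laser regimes: overall Raman intensity is 10× larger at 532 nm; the
CH-stretch region carries relative weight 1.0 at 532 nm (making it the
dominant band group) and 0.08 at 785 nm (sub-dominant, the 1440 cm⁻¹
band dominates); carotenoid bands are resonance-boosted 3× at 785 nm.
With these choices the dominant-peak intensity ratio between lasers is
≈ 12 — an order of magnitude, as observed for such instruments.

Cells add carotenoid bands (1006/1155/1520 cm⁻¹, HWHM 6, relative
weights 0.6/0.8/1.0), chlorophyll bands (six components across
800–1200 cm⁻¹), optional protein bands (550, 1004, 1245, 1275 cm⁻¹ and
amide I at 1660 cm⁻¹) and a broad fluorescence baseline
(0.8·exp(−ν/1200) + 0.2, amplitude 2000 counts at 532 nm, 5 % of that at
785 nm).  Photobleaching multiplies the fluorescence and chlorophyll
terms by exp(−t/τ) with τ = 25 s, and the carotenoid bands by
exp(−t/τ_car) with τ_car = 10 s: resonance-enhanced carotenoid signals
photodegrade much faster than the broadband autofluorescence, which is
what makes the 1520 cm⁻¹ band drop far below the lipid bands within the
30–75 s bleach window while some fluorescence remains.

Noise is additive Gaussian (detector-dominated regime).  The default
per-accumulation amplitude for cells is 2 % of the profile's 1440 cm⁻¹
peak height, and single-cell acquisitions average 10 accumulations
(within the 10–25 used in practice), so the effective noise is
2 %/√10 ≈ 0.6 % of the reference peak.  Standards default to a single
accumulation so tests can set the noise level explicitly.

## Background subtraction and its residual distortion

The background estimate is a centred moving average (default width
300 cm⁻¹ ≈ 101 grid points, reflect padding) subtracted from the
spectrum; the same filter is applied to standards and unknowns by
contract.  The filter passes broad fluorescence but also redistributes a
few per mille of each band's own area into its neighbourhood, which
biases the fitted I₁₆₅₀/I₁₄₄₀ of a subtracted spectrum upward by ≈ 2 %
(the 1440 band's mass enters the 1650 window's local average).  This
distortion is deliberately *not* corrected: it is constant across
samples, exactly as in the experimental protocol, and is far smaller
than the quantities of interest.  Model-based baseline estimation
(asymmetric least squares etc.) is out of scope.

## Quality control

**Protein screen.**  The 1650 cm⁻¹ band overlaps the protein amide I
band, so contaminated spectra must be rejected before ratio analysis.
Candidate peaks in the marker windows 550 ± 10, 1004 ± 5 and
1220–1300 cm⁻¹ are local maxima whose prominence exceeds 5σ (the search
is padded ± 15 cm⁻¹ so prominence is judged against the local baseline,
not the window edge); each candidate is refined by a single-Lorentzian
fit and flags the spectrum when the fitted height exceeds 5σ.  Two
refinements reflect genuine band overlaps in lipid spectra: peaks inside
1252–1268 cm⁻¹ (the =C–H cis deformation of unsaturated lipid) and
1290–1310 cm⁻¹ (the CH₂ twist flank) never count as protein, and a peak
near 1004 cm⁻¹ is attributed to carotenoid when the partner carotenoid
band at 1155 cm⁻¹ is present at comparable height.  The noise scale is
the supplied σ or a robust estimate (1.4826·MAD of the band-free
1800–2600 cm⁻¹ region), floored at 0.1 % of the 1440 cm⁻¹ peak — the
residual-distortion scale of the background filter — which keeps the
screen invariant under global intensity rescaling.

**Photobleach check.**  area(1520) / min(area(1440), area(1650)) must be
below 0.5 ("far below" quantified as one half; configurable).  The
carotenoid band is fitted in a wide 1490–1560 cm⁻¹ window because it
sits on the residual dip the background filter leaves between the two
strong lipid bands.

**Detection gating.**  Least squares on a pure-noise window manufactures
spuriously positive areas (the amplitude is bounded below by zero).  A
secondary band (1650, 3003, 1520 cm⁻¹) therefore counts as absent — area
exactly zero — unless the raw window signal (max − median) stands 4σ
out and the fitted height clears the same level.  At the default 2 %
noise this puts the weak olefinic 3003 cm⁻¹ band of a monounsaturated
lipid below the detection limit; the I₃₀₀₃/I₁₄₄₀ ratio is therefore most
useful on low-noise or averaged spectra.

## Peak fitting

Each analysis window (1380–1500, 1600–1700, 2800–3100 cm⁻¹, the latter
with components at 2850/2885/2930/3003 cm⁻¹) is fitted with the stated
number of Lorentzians plus a constant offset by Levenberg–Marquardt
(lmfit), initialized at the canonical band centres with HWHM 8 cm⁻¹ and
heights read off the data; up to five seeded random-perturbation
restarts handle non-convergence, so fits are deterministic given data
and initialization.  The explained-area fraction (model signal area over
positive data area in the window) is reported and a warning is emitted
below 99.9 %; the criterion is a quality gate, not a failure mode.
Ratios are computed from fitted areas and are invariant to overall
intensity rescaling.

## Calibrations

* **ratio → C=C** and **ratio → N_C=C/N_CH₂**: ordinary least squares.
  The packaged surrogate for a real-instrument calibration is the OLS fit
  over the eight-strain reference table (slope 1.642, intercept −0.045,
  r² = 0.997 for C=C), applicable to 532 nm data.  Models carry an
  excitation tag that `quantify` enforces; negative property estimates
  (possible through the OLS intercept) are clipped to zero with a
  warning.
* **melting point → ratio**: a four-parameter logistic, decreasing in
  melting point, fitted by seeded multi-start least squares with the
  relative weighting customary for 4PL calibration curves (per-point σ
  proportional to the response, floored at 5 % of the maximum so
  zero-response points keep finite weight — the response spans more than
  a decade).  Inversion is closed-form on the monotone branch; values at
  or beyond an asymptote raise a range error.  With the default panel
  the inversion of ratio 0.52 lands at ≈ 8–9 °C, near the low edge of
  the 10 ± 2 °C benchmark: a symmetric logistic cannot simultaneously
  follow the gentle monounsaturated plateau (0.5–13 °C) and the exact
  zeros of the saturated standards, and the polyunsaturated standards'
  melting points are themselves non-monotone in unsaturation (DHA melts
  above EPA).
* **Mixtures**: band areas are mole-additive, so a weight-fraction
  mixture behaves as a single species with mole-averaged N_C=C and
  N_CH₂; `mixture_ratio` gives the closed-form expected ratio, which is
  continuous and monotone in the weight fraction and bracketed by the
  pure-component ratios.
* **Known-chain inversion**: for a sample of known methylene count (a
  pure standard), the C=C count is recovered as `ratio · N_CH₂ / κ` —
  the exact inversion of the generator contract.  A single linear
  ratio↔C=C calibration across chain lengths is only approximate (the
  ratio is linear in N_C=C/N_CH₂, not in N_C=C), which is why the
  parameter-recovery analysis uses the chain-length-normalized route.

## Fatty-acid registry

Eleven even-numbered standards (C12:0, C14:0, C16:0, C16:1, C18:0,
C18:1, C18:2, C18:3, C20:4, C20:5, C22:6) with melting points from
standard chemistry references, spanning 0–6 double bonds.  Structural
arithmetic assumes straight-chain, methylene-interrupted, all-cis free
fatty acids: N_CH₂ = n_C − 2 − 2·N_C=C (terminal CH₃ and carboxyl carbon
excluded), verified in the tests against an explicit group-list
structure builder.  Per-residue averages are reported as-is for TAGs;
odd-chain, branched and hydroxylated acids are out of scope.

## Scenes, maps and localization

Scenes are continuous 2-D fields (origin lower-left, x right, y up):
circular lipid droplets and pigment patches on a uniform background.  A
pixel's composition integrates the scene over a Gaussian lateral PSF
whose FWHM is the excitation's Airy spot diameter 1.22·λ/NA (0.811 µm at
532 nm, 1.197 µm at 785 nm for NA 0.8); the diffraction-limited lateral
resolution is 0.42·λ/NA (0.279 / 0.412 µm).  The axial dimension is
excluded: focus is an instrument action, and scenes are 2-D.  The
axial-resolution constant is not implemented because no single
convention reproduces the instrument's printed values.

Band images integrate each background-subtracted pixel spectrum over a
window (default lipid band 2800–3000 cm⁻¹ at 532 nm, 1380–1500 cm⁻¹ at
785 nm).  Component maps use protein 995–1012, carotenoid 1505–1535 and
lipid 1380–1500 cm⁻¹; each channel is zeroed below its own noise floor
(median + 5·robust σ), normalized to its maximum, and the composite
assigns each pixel its largest normalized component — invariant to
global rescaling.

Localization samples a 10 × 10 map of the current window, re-centres on
the brightest lipid pixel (ties break at the lowest row, then column
index) and halves the window, iterating while the window exceeds the
1 µm stop size — exactly ⌈log₂(start/stop)⌉ iterations — then extracts
the single spectrum at the final centre.  If the first map's maximum
does not stand 5 robust σ above the median, localization fails (uniform
scene, nothing to find).  On noise-free scenes the distance to a planted
droplet is non-increasing across iterations up to the half-pixel
quantization of each map.

## Problem sizes and determinism

The test suite and the acceptance script use the study's own scales: the
11-standard panel, 20 replicates per standard at 2 % noise for parameter
recovery, 3 replicate cells for the reference-cell quantification
(averaging replicate acquisitions is standard practice and what the
accumulation protocol emulates), 50 random droplet scenes for
localization and 30-cell panels for classification.  Every stochastic
step is seeded; generators are bit-reproducible under a fixed seed.

## What the synthetic data does and does not show

The generator reproduces the band structure, the two-laser intensity
regimes, pigment interference, fluorescence bleaching and detector
noise, so green tests demonstrate that the pipeline recovers what the
model plants — calibration slopes, band ratios, droplet positions —
under realistic interference.  It does not model Raman cross-section
physics, resonance effects beyond a scalar carotenoid boost, water/
quartz background, cosmic-ray spikes, instrument drift, or cell-to-cell
morphological variation; passing tests therefore validate the analysis
chain, not instrument performance on real cells.  The reference-cell
ratio anchors (0.52 / 0.30) are built into the generator's coupling
constants, so their recovery is a pipeline-integrity check, not an
independent reproduction; the downstream property estimates and all
property-based suites carry the real evidential weight.
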