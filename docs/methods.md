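# Methods

`retispec` implements a retinal hyperspectral analysis chain — RGB-to-spectrum
calibration on a 24-patch color target, per-pixel spectral reconstruction,
standardized five-window ROI sampling, group-level spectral statistics, and a
patient-level ORI-vs-HSI classification comparison — driven end to end by a
seeded synthetic data generator.  This note records the model, the defaults
that matter, and the design choices that were genuinely open.

## Spectral axis and colorimetry

All spectra live on a uniform wavelength grid, by default 380–780 nm at 1 nm
(401 bands).  Colorimetry uses an analytic multi-lobe Gaussian fit of the CIE
1931 2° standard observer (accurate to ~1% of peak) and, for "D65", a smooth
Planckian radiator at 6504 K normalized to unit mean as a stand-in for CIE
daylight.  The white point is always computed from the same observer and
illuminant tables, so Lab conversions, reference XYZ values, and ΔE00 reports
are mutually consistent by construction; no external spectral tables are
required.  CIEDE2000 follows the CIE formula with kL = kC = kH = 1 and is
verified against the canonical published pair list and an independent
implementation.

## Calibration model

The camera-to-spectrum mapping has two pseudo-inverse-fitted stages:

1. **Polynomial color correction.**  The camera triplet is linearized
   (inverse power 2.2 by default; sRGB decode and identity are selectable),
   expanded into all monomials `r^a g^b b^c` with `a+b+c ≤ 3` (20 terms,
   ordered by ascending degree then descending exponents; the order is
   serialized with the model), and mapped to reference XYZ by
   `M = A·pinv(V)`.
2. **PCA spectral estimation.**  The 24 target reflectance spectra are
   decomposed into a mean spectrum plus `k` orthonormal principal components
   (`k = 12` by default — small enough that the score regression on 24
   patches stays well-posed, large enough to exhaust the target's visible
   variance), and a second pseudo-inverse regression maps the same
   third-order expansion of the corrected XYZ to the `k` scores.

A reconstructed spectrum is `mean + scores·eigenvectors`, clipped to
[0, 1.5] with the clipped fraction logged.

**Pseudo-inverse truncation.**  A third-order expansion fitted on 24 patches
is severely ill-conditioned; the small singular directions encode
interpolation wiggles that explode on colors far outside the target's gamut
— and fundus tissue is far outside any color-target gamut.  In exploratory
runs the machine-precision solution was so unstable there that it *reversed*
the sign of the reconstruction's response to a long-wavelength reflectance
increase.  `fit_calibration` therefore truncates singular values below 3% of
the largest by default; at this truncation the reconstruction Jacobian has
the physically expected structure (long-wavelength bands respond to the red
channel, short-wavelength bands to blue, cross-terms near zero, checked
across target seeds).  The low-level `fit_correction`/`fit_basis` default to
the untruncated pseudo-inverse so that exactly representable systems are
reproduced to machine precision and the solution coincides with the
normal-equations solution on full-rank systems.

## Synthetic data generator

The generator defines the study conditions the tests certify.

- **Calibration target**: 6 achromatic levels plus 18 chromatic patches
  built as logistic functions of smooth Gaussian bumps and spectral edges
  (widths ≥ 20 nm), keeping all spectra in (0, 1) with bounded band-to-band
  change.  Reference XYZ is computed from the reflectances under the
  configured illuminant, mirroring spectrometer measurement of a physical
  target.
- **Camera**: three Gaussian sensitivities centered at 610/545/460 nm
  (σ = 38/33/28 nm), normalized so unit reflectance renders white; gamma 2.2
  encoding; additive Gaussian noise on the linear signal (SD 0.01,
  about 1% of full scale — a generic fundus-camera stand-in).
- **Fundus phantoms** (512×512 by default): three tissue classes —
  background fundus, vessel arcades, fovea — with smooth hemoglobin-like
  reflectance curves (absorption dips at 542/577 nm, steep red rise).
  Vessels are superior/inferior elliptical arcade arcs with seeded geometry
  jitter; the fovea is a soft dark disc at the image center; a smooth ±2%
  multiplicative texture field adds spatial variability.  The truth field is
  low-rank (`texture · Σ weights·class_spectra + additive`), so windows or
  the full 512×512×401 cube materialize on demand and every phantom exposes
  exact ground truth.
- **Disease effect**: a clamped logistic ramp, exactly zero at and below
  550 nm, rising to a plateau by ~700–780 nm, scaled 0 / 0.5 / 1.0 ×
  amplitude (default 0.10 reflectance units) for Normal / MCI / Dementia.
  This reproduces the monotone severity ordering and long-wavelength
  localization the analysis is designed to detect, with group separation of
  roughly 2–3 within-group SDs at the plateau.
- **Subject variability**: five smooth spectral modes — overall brightness,
  a dominant short-wavelength pigmentation mode (SD 0.05 at 450 nm), mid-
  and long-wavelength bumps, and a tilt — drawn per subject, plus 0.3× and
  0.15× scaled draws per eye and per image.  Pigmentation dominating the
  short wavelengths mirrors real fundus color variation and places the
  heaviest nuisance variance outside the disease band.
- **Cohort**: by default the published composition — 137 subjects (49/54/34
  Normal/MCI/Dementia), 274 eyes, 3256 images (1254/1320/682) — with sex
  counts and uniform age/MMSE draws within each group's printed ranges.
  Arbitrary compositions are accepted; infeasible ones (fewer images than
  subjects) are rejected.

`truth_roi_spectra` computes ground-truth subject-level ROI spectra
analytically (shared geometry, no rendering) and exists for large
statistical simulations: 200-replicate null calibrations would be wasteful
through the full rendering path.

What the phantoms do **not** emulate: anatomically realistic vessel trees,
optic disc, media opacity, illumination falloff, eye movement or focus
artifacts.  Passing tests certify the pipeline's statistical and numerical
behavior under controlled spectral structure, not clinical performance.

## ROI scheme

Five square windows — S1, S2 above, F on, I1, I2 below the fovea — of side
240 px on a 512 px image, centers displaced ±136 px vertically and
horizontally from the fovea.  Geometry is configuration, scaled
proportionally for other image sizes; windows that would leave the image are
an error naming the offending ROI (never clamped), and the necessary overlap
of 240 px windows on a 512 px image is logged.  The fovea center is taken
from phantom metadata; a fallback detector (darkest smoothed region near the
image center) is provided.  ROI spectra are unweighted per-band means,
accumulated in float64.

## Group statistics

All statistics operate on subject-level spectra: repeat images and both eyes
are averaged per subject first, so subjects are the units of inference and
pseudo-replication is avoided.  Envelopes are mean ± SD per (ROI, group),
optionally stratified by sex or age decade (a half-range envelope is
selectable).  Per-band comparisons are Welch's two-tailed t-test by default
(pooled-variance selectable), with raw p < 0.05 flags reported alongside
Benjamini–Hochberg q-values — the raw flags mirror the uncorrected analysis
convention, the q-values accompany them as the defensible alternative.

Because subject deviations are low-rank, per-band test outcomes are heavily
correlated across bands: in a single cohort the flagged fraction of a null
band range is essentially all-or-nothing.  Power and false-positive rates
are therefore estimated by averaging over replicate cohorts (200 replicates
at 20 subjects/group in the acceptance checks), which is also how the
reported type-I error of ~0.05 is computed.

**Known limitation — spectral crosstalk.**  Reconstruction from three
channels has three degrees of freedom: any group difference in the camera
signal propagates into all reconstructed bands through the basis functions.
On reconstructed spectra the >550 nm effect therefore leaks a correlated
(much smaller) difference into sub-500 nm bands, which the per-band test
detects at well above the nominal rate.  Band-localization claims are
accordingly validated on ground-truth spectra; wavelength localization of
effects measured on RGB-derived reconstructions should be interpreted with
this crosstalk in mind.

## Classification harness

Splits are subject-level 70/10/20, stratified by group, independently
re-drawn per fold ("5 folds" = 5 seeded repetitions); an automated audit
asserts that no subject crosses partitions.  Augmentation (training set
only) composes random horizontal/vertical flips, rotations within ±15°,
middle-channel ("green channel") extraction applied to half the augmented
copies, and pixel noise (amplitude 0.01); morphological opening is available
but off by default.  Both modality arms share splits, seeds, augmentation,
and backend, so differences are attributable to the input representation
only.

The desk-scale backend is a small MLP head (one hidden layer of 16 units) on
bicubic-downscaled 8×8×3 inputs, trained with Adam (batch 32) and early
stopping on validation loss with patience 10 — the published fine-tuning
protocol's optimizer and stopping rule.  The published recipe's learning
rate (1e-4) and 50-epoch cap target ImageNet-scale fine-tuning and would
underfit a from-scratch head on a few hundred samples, so the desk default
raises them to 1e-3 and 200 epochs; `transfer_recipe()` returns the
published values for plug-in backends, and any callable can replace the
backend for heavier architectures.

ORI inputs are the rendered RGB images; HSI inputs are reconstructed cubes
restricted to 550–780 nm and reduced to three channels by thirds-averaging
(parameter-free; named-band and spectral-PCA reductions are selectable).
The reflectance reductions are normalized by a *fixed* linear clip rather
than per-image min-max, because per-image rescaling would erase the absolute
reflectance level that carries the group signal.  Since the HSI input is a
deterministic transform of the same render, it cannot add information; its
measured advantage is representational — the band selection concentrates the
long-wavelength signal, and under the green-channel augmentation the ORI
arm's middle channel is signal-poor while the HSI reduction's middle channel
is itself a long-wavelength band.

Per-class metrics are one-vs-rest precision, recall, specificity, and F1
from the confusion matrix, with undefined ratios reported as NaN (never 0)
and both macro and support-weighted averages emitted.  Modalities are
compared by fold-paired two-tailed t-tests per metric; an all-zero
difference vector reports t = 0, p = 1 rather than a 0/0.

## Numerical and degenerate-input conventions

- Pseudo-inverse truncation: machine precision in the low-level fitters,
  3% of the largest singular value in `fit_calibration` (above).
- Reconstructed reflectance clipped to [0, 1.5]; clipped fraction logged.
- Single-band range selections and single-subject groups are valid (SD
  envelope is zero); empty (roi, group) cells are omitted with a warning.
- Off-grid montage wavelengths snap to the nearest band with a warning;
  off-grid range bounds are errors.
- Cubes are float32 (a full 512×512×401 cube is ~420 MB); ROI means and all
  statistics accumulate in float64.
- Problem sizes in the acceptance checks: 20 subjects/group for the
  spectral-recovery cohort (one 512 px image per subject), 200 replicate
  cohorts for null/power estimation, and 20 subjects/group × 2 images at
  64 px with 5 folds for the classification comparison — chosen so the full
  chain, including per-pixel reconstruction, runs comfortably on a single
  CPU while keeping group-level estimates stable.
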