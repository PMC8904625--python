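# Methods

## Refraction representations

Prescriptions are stored in the negative-cylinder clinical convention
(`SpheroCylinder`); positive-cylinder input is transposed on construction and
the axis canonicalized into [0, 180).  The power-vector form
`(M, J0, J45)` is the working representation for all averaging and
statistics, because it is a vector space (means of prescriptions are
meaningful) while sphere/cylinder/axis is not.

The paraxial link between a power vector and second-order Zernike
coefficients on a pupil of radius `r` mm (coefficients in µm) is

```
c(2,0)  = -M  · r² / (4√3)      c(2,±2) = -{J0, J45} · r² / (2√6)
```

with the sign convention under which a myopic eye has a positive defocus
coefficient.  The inverse (`zernike_to_sc`) optionally adds the standard
paraxial spherical-aberration term, `M += 12√5·c(4,0)/r²`, which matches the
wavefront curvature at the pupil center instead of the least-squares
defocus; it is **off by default** — the frame refraction used by the dynamic
optimizer is then the pure second-order reading, which is also what the
simulator inverts exactly.  Both modes are available because the choice is a
genuine modelling ambiguity when reading "the closest sphero-cylindrical
correction" off a wavefront that contains spherical aberration.

**Chromatic correction.**  The chromatic difference of refraction of the eye
is spherical, so the correction is a configurable offset on `M` only.  The
default offset function is the reduced-eye dispersion formula
`D(λ) = 1.68524 − 633.46/(λ − 214.102)` (diopters, λ in nm, zero near
589 nm), applied as `ΔM = D(λ_ref) − D(λ_meas)`; for a near-IR aberrometer
(850 nm) referred to the photopic 555 nm this is ≈ −0.86 D.  An identity
model is provided and is the package default, since the synthetic generator
emits coefficients already referred to 555 nm.  Candidate corrections live
in reference-wavelength space; before subtraction from a measured wavefront
they are mapped back to the measurement wavelength (the inverse offset).

## PSF computation

The pupil function is sampled on an `N×N` grid (default 256) with the pupil
spanning `pupil_fill_fraction` (default 0.5, i.e. 2× zero-padding) of the
array, giving 128 samples across a default pupil.  The PSF is
`|FFT(A·exp(i2πW/λ))|²`, unit-sum normalized, with angular pixel scale
`Δθ = λ/(N·dx)`; at 4 mm / 555 nm this is 0.238 arcmin/pixel and the field
of view is ±30.5 arcmin.  Note that `Δθ` depends only on pupil diameter and
fill fraction — doubling `grid_size` refines the *pupil* sampling at
constant PSF pixel scale, and the convergence suite verifies that doubling
128→256 moves every metric by < 1 %.  A 128² grid (64 pupil samples) is
used throughout the test suite and the acceptance script; it is ~4× faster
per PSF and within a fraction of a percent of the 256² values.

Metrics are evaluated inside a `psf_window` (default ±30 arcmin, clamped to
the grid) so wrap-around energy at the array edge cannot leak into
entropy/variance-type metrics.  Trial corrections far from the optimum can
produce PSFs whose half-max envelope leaves the window; in batch scoring
such failures become NaN and rank last, and an optimizer errors only if a
metric fails on *every* candidate.  The monochromatic PSF is computed at a
single reference wavelength (polychromatic imaging, Stiles–Crawford
apodization and scatter are out of scope).

## The eight image-quality metrics

All metrics compare the eye's PSF with the diffraction-limited PSF of the
same pupil and wavelength; SR, STD, NS, VSX and VSMTF are self-normalized to
exactly 1 for the aberration-free eye.

* **Entropy** uses the natural logarithm on the unit-sum PSF restricted to
  the analysis window, with `0·log 0 := 0`.
* **IV** is the variance of windowed PSF intensities (mean of squares minus
  squared mean); the tests pin it to the equivalent Parseval
  frequency-domain form.
* **NS** weights the PSF by a bivariate Gaussian of σ = 1 arcmin (the
  conventional value in the neural-sharpness literature; configurable).
* **VSX/VSMTF** use a radial Mannos–Sakrison neural contrast sensitivity
  `A(f) = 2.6(0.0192 + 0.114f)·exp(−(0.114f)^1.1)` (f in cycles/degree,
  band-pass, peak ≈ 8 cpd).  No specific CSF is canonical for this purpose;
  every recovery property in the test suite holds for any band-pass CSF,
  and the parameters are configurable.
* **FWHM** is the mean over 36 azimuthal cross-sections through the peak of
  the full width at half maximum, with the half-max crossing taken at the
  **outermost** crossing on each side (linear interpolation, 0.25 px radial
  steps).  For a unimodal PSF this is the textbook FWHM.  The outermost-
  crossing rule matters: a speckled or ringed PSF has a narrow brightest
  speckle, and a first-crossing FWHM would score badly aberrated PSFs as
  "sharp", inverting the metric's orientation.  Even so, peak-referenced
  FWHM is intrinsically non-monotone in defocus near the ring-formation
  transition (≈ 0.25 µm of c(2,0) on a 4 mm pupil), where the envelope
  around the coherent core briefly shrinks — verified at 512² sampling.
  This is a property of the metric, not of the implementation, and is the
  reason FWHM is the weakest of the eight in the optimizers.

FWHM and entropy are minimized, the rest maximized; the orientation is
encoded once on `MetricSpec` and never re-decided at call sites.

## Optimizers

**Static search.**  Offsets of ±1.5 D sphere and ±1 D cylinder in 0.25 D
steps and ±20° of axis in 5° steps around the base prescription give
13×9×9 = 1053 raw combinations (within the nominal 1215 bound); after
clamping trial cylinders to ≤ 0 and collapsing the axis of zero-cylinder
candidates, duplicates are removed preserving enumeration order.  Every
candidate is subtracted from the wavefront (orders 3–4 pass through), the
residual PSF scored, and the prediction per metric is the unweighted mean
power vector of the best `ceil(0.05·N)` candidates.  Averaging the top
quantile instead of taking the single extremum keeps near-tied prescriptions
in the estimate; the one structural consequence is that a *perfect* eye
recovers `M` exactly (by symmetry of ± defocus candidates) but picks up a
small (< one grid step) astigmatic component from the near-tied
small-cylinder candidates clustered around the base axis.

**Dynamic selection.**  After blink filtering (flagged frames dropped; a
pupil guard also rejects frames outside 1.5–9 mm as artifacts) each frame's
refraction is quantized to clinical steps (0.25 D sphere/cylinder, 5° axis;
configurable), subtracted from the frame's own wavefront at the frame's own
pupil, and the residual PSF scored.  The prediction per metric is the mean
power vector over the top `ceil(0.20·N)` frames.  Ranking ties are broken
deterministically by enumeration order (candidate sphere/cylinder/axis
ascending; frame time ascending); both optimizers are fully deterministic.
A metric-weighted mean is available behind a flag but off by default — the
procedure specifies an unweighted mean.

Selection fractions are interpreted as `ceil` with a minimum of one
selected.  `top_fraction=1` degenerates to the unselected grid/frame mean,
which is also the "autorefractor readout" baseline used in the evaluation.

## Agreement statistics

Differences are oriented predicted − subjective.  MBE, MAE, the 95 % limits
of agreement `LOA = 2·SD(diff)` (sample SD, n−1 — the Bland–Altman
convention; the alternative n denominator differs by < 1 % at n = 50) and
inclusive threshold percentages (|diff| ≤ 0.25/0.5 D) are reported per
component.  No inferential statistics are attached.

## Synthetic acquisitions

The generator emulates a 10 s binocular open-view acquisition at 8 frames/s
(80 frames) of an adult eye:

| process | default | rationale |
| --- | --- | --- |
| microfluctuations | 0.10 D at 0.1–0.6 Hz + 0.05 D at 1–2.3 Hz, random phase | the two-band structure and magnitudes reported for accommodative microfluctuations in adults |
| myopic excursions | Poisson 0.25/s, 0.75 D, 1.5 s raised-cosine | instrument-myopia episodes; sized so the unselected frame mean is biased ≈ −0.15 D, the scale reported for handheld wavefront autorefractors |
| excursion optics | +0.15 µm split 60/40 between horizontal coma and spherical aberration | accommodation measurably degrades high-order optics; this is the physical handle that lets an IQM identify excursion frames |
| tear-film drift | 0.01 µm/s on trefoil + SA, reset at blinks | inter-blink optical degradation |
| blinks | every 4 s (± 0.2 s), 0.25 s gaps | flagged frames with no wavefront |
| measurement noise | 0.01 µm per coefficient | per-frame Zernike repeatability of video aberrometry |
| baseline HOA | 0.02–0.05 µm (trefoil, coma, SA), ×U(0.5,1.5) per eye | typical adult high-order RMS ≈ 0.08 µm at 4 mm |
| subjective noise | 0.25 D on M, 0.10 D on J0/J45 | clinical test–retest repeatability of subjective refraction |

Cohorts draw spheres from N(−0.5, 2) D clipped to [−6.25, +3] and
half-normal cylinders clipped to [−3, 0] — the refractive spread of the
study population the package is modelled on — with uniform axes and pupils
of 3.5–5 mm.  All randomness flows from one seed through spawned
`SeedSequence` children, so any single eye is reproducible alone.

What the simulator does *not* model: real accommodation dynamics (it is a
phenomenological signal, not a control loop), correlation between fellow
eyes, pupil-size dynamics, device-specific centroiding noise, or any link
between refractive error and HOA magnitude.  Passing tests therefore show
that the selection machinery recovers a plateau refraction whenever
excursions degrade measurable image quality — the mechanism the dynamic
approach presumes — not that clinical accuracy figures transfer to real
patients.

On the bias comparison used in the recovery tests: the paired "subjective"
value is truth plus zero-mean noise, and at n = 50 the cohort mean of that
noise (σ ≈ 0.035 D) is a common-mode offset on the MBE of *both* estimators
that can mask or mimic the bias difference between them.  The
direction-of-effect test therefore compares both estimators against the
generating truth, which isolates the estimator property; the acceptance
script reports the vs-subjective numbers alongside.

## Numerical choices and limitations

* Grid sizes are powers of two ≥ 128; fill fraction ≤ 0.5 guarantees ≥ 2×
  padding.  The diffraction-limited PSF is cached per (pupil, λ, sampling).
* PSF peak ties (degenerate maxima) are broken by proximity to the
  intensity centroid.
* CSV output uses `%.17g` and reading uses round-trip float parsing, so
  file round-trips are bit-exact.
* The measured per-frame pupil is used by default for each frame's PSF and
  its diffraction-limited reference.  A fixed analysis diameter is available
  (`analysis_pupil`): wavefronts are rescaled to the smaller concentric
  pupil by an exact subaperture refit (`rescale_pupil`), with piston/tilt
  discarded; frames whose measured pupil is smaller than the analysis
  diameter are rejected.
* Vertex-distance effects, prism, near additions and polychromatic imaging
  are out of scope.
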