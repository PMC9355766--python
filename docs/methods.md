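# Methods

This note records the models implemented in `dentinemp`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Measurement models

### INAG

The index of aging compares the mean intensities of a co-registered
SHG/TPEF pair: INAG = (Ĩ_S − Ĩ_T)/(Ĩ_S + Ĩ_T). The tilde is read as the
spatial mean over valid pixels, which makes the scalar index a bijection
of the mean-intensity ratio r = Ĩ_S/Ĩ_T via INAG = (r−1)/(r+1); the
package keeps the two consistent to machine precision and exposes both.
Because "average ratio" is ambiguous, `shg_tpef_ratio` also offers the
mean-of-pixel-ratios reading (`pixelwise=True`); note the two differ on
heterogeneous images. The spatially resolved map applies the same
quotient pixelwise after Gaussian smoothing of each channel (default
1 µm) — the quotient amplifies noise where both channels are dark — and
masks pixels whose summed intensity falls at or below a floor (default 1%
of the joint maximum). The scalar summary is computed from channel means,
not by averaging the map; both are reported and labeled.

### Peritubule size

Longitudinal SHG views show peritubular sheaths as quasi-parallel bright
stripes. The dominant axial orientation comes from Otsu thresholding
followed by straight-line Hough voting (0.5° grid, squared-accumulator
scoring so a few long lines beat many short ones, parabolic peak
refinement). Size is then measured on intensity profiles sampled by
bilinear interpolation along lines perpendicular to that orientation
(default 9 sections spread across the field, 0.25-px steps), lightly
median-filtered over a 3-px window; local minima with prominence ≥ 10% of
the profile's dynamic range are the valleys, and the size is the median
consecutive-valley spacing in µm. This operationalizes "size" as the
stripe *period* (ridge plus gap), which is what valley spacing measures;
it is therefore larger than a transversal lumen diameter would be.
Profiles are snapped to 9 significant digits of their dynamic range
before peak finding so that flat valley floors form a single plateau
rather than many one-ulp micro-minima. The estimator is pixel-limited:
accuracy is within one pixel (0.35 µm at the default sampling) across
periods 3–7 µm and arbitrary orientations.

An image with no resolvable anisotropy (constant, isotropic noise, or a
balanced orientation mixture) raises `NoDominantOrientationError`; the
check is the weighted axial resultant length of structure-tensor
orientations (floor 0.2), not local coherence, because local gradients of
pure noise are themselves locally coherent at the smoothing scale.

### Structural dispersion

Local orientations come from the structure tensor: gradients of the
Gaussian-smoothed image (σ = 0.5 µm, below the stripe scale) are
outer-product averaged with a larger Gaussian (σ = 2 µm, above it).
Orientations are axial (180°-periodic); all statistics double the angles.
SD is defined as the coherence·energy-weighted RMS axial deviation from
the weighted axial circular mean, wrapped to ±90°. This statistic is
bounded by 90°, reduces to the ordinary standard deviation for tight
distributions (a field rendered with 10° orientation jitter measures
SD ≈ 10°), and evaluates to 180/√12 ≈ 52° for uniformly random
orientations. The classic circular-standard-deviation formulas were
rejected deliberately: √(−2 ln R̄) is unbounded and √(2(1−R̄)) saturates at
40.5° for axial data, which would make the disorganized class (> 40°)
practically unreachable. Classes: organized SD ≤ 20°, disorganized
SD > 40°, partial in between.

Angle convention everywhere: degrees, counter-clockwise from the image
row axis, origin at the top-left pixel, axial equivalence mod 180°.

### Polarimetric ρ

The forward model is the cylindrical-symmetry SHG response

I(Δ) = K · p(x, y) · { sin²(2Δ) + [sin²Δ + ρ·cos²Δ]² },

with Δ = α − θ (incident polarization minus fiber orientation) and
p the local scatterer density. Three states are acquired (default
0°, 90°, 60°). In the canonical frame (fibers along one state) the
parallel/perpendicular ratio gives |ρ| = √(I_par/I_perp) and the oblique
state votes on the sign by model discrepancy. Off the canonical frame the
ratio of the two states nearest Δ = 0/90° still pins ρ to the two roots
of a per-pixel quadratic (K·p cancels in every ratio, so no inter-image
calibration is needed); `rho_map` solves it in closed form and lets the
third state select the root, making noiseless recovery exact for any
fiber orientation. `rho_magnitude`/`rho_sign` retain the simple
canonical-frame semantics.

One genuine identifiability limit: the response is even in Δ, so a fiber
orientation that makes two states mirror-symmetric about the axis
(θ ≡ 30°, 45°, 75° mod 90° for the default states) collapses the stack to
a single independent ratio and ρ becomes exactly two-valued — e.g.
ρ = −1.25 and ρ = +1.483 produce identical noiseless stacks at θ = 30°.
No estimator can break this tie, so such geometries raise
`GeometryError` (tolerance 3°) rather than return an arbitrary branch.
The pipeline logs and skips ρ for affected regions; experimenters avoid
these geometries by rotating the sample or the polarization basis.
Summary statistics are computed pixelwise then averaged over unmasked
pixels (default floor: 1% of the maximum perpendicular intensity); an
image-averaged-intensities variant is available via `method="mean"`.

## Synthetic data

The generator emulates exactly the features the analysis relies on:

- stripe fields with controllable period (= ground-truth peritubule
  size), orientation, duty cycle (default 0.45) and raised-cosine ridges
  over a darker valley floor (contrast 0.9), on 512 px / 180 µm fields
  (0.35 µm/px — ≥ 11 px per period for the smallest sizes of interest);
- smooth orientation jitter, implemented as a Gaussian-correlated random
  displacement of the stripe phase (correlation length 7 µm) whose
  along-stripe derivative is rescaled so the pointwise tilt of the local
  stripe direction has exactly the requested standard deviation — this is
  what makes SD recovery quantitatively testable;
- TPEF/SHG pairs sharing one geometry with the SHG channel scaled by the
  target mean ratio; detector noise is Poisson photon noise plus Gaussian
  read noise, quantized to 16 bits. Fully noiseless renders skip
  quantization and return continuous intensities so that analytic
  identities (ratio exactness, ρ round trips) hold to machine precision;
- polarimetric stacks following the forward model above, with an optional
  uniform baseline so inter-ridge pixels carry signal;
- cohorts: per-specimen ground-truth width/INAG/ρ drawn as
  line(age) + N(0, σ), the per-region intensity ratio back-solved from
  INAG as r = (1+INAG)/(1−INAG) (requests outside (−1, 1) are rejected),
  five regions per specimen with orientations cycled through
  {0°, 20°, 60°, 90°, 150°} — chosen off the mirror-degenerate set.

Defaults define the emulated study: 9 specimens aged 19–82 (4 M / 5 F;
the source cohort's printed sex counts are internally inconsistent, so
both the size and the split are configuration), residual standard
deviations (0.4 µm width, 0.04 INAG, 0.15 ρ) back-derived from the
reported correlation strengths (R ≈ 0.86/0.83/0.95 at an age SD of
≈ 21.6 yr) so default cohorts scatter realistically, and modest detector
noise (≈ 2000-count TPEF mean, unit photon gain, 2-count read noise).

Not emulated: optical point-spread function and 3-D sectioning, enamel
and the dentine–enamel junction, tubule branching and density variation,
depth-dependent attenuation, pathology. Passing recovery tests therefore
demonstrates correctness of the measurement chain on its geometric and
statistical assumptions, not robustness to every property of real
micrographs.

## Statistics

Specimens, not regions, are the regression units (region-level fits are
available by passing the region table directly). Fits are ordinary least
squares; Pearson R with the two-sided t-test p-value; no
multiple-testing correction is applied, matching the emulated analysis.
Relative change between two ages is evaluated on the fitted line as
change in magnitude — for a negative index, "58% larger" means 58% more
negative — with the signed variant exposed and zero crossings flagged.
The Mann–Whitney U test uses the exact null for small tie-free samples
and the tie-corrected normal approximation otherwise, recording which.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configuration + seed reproduces
images, tables and CSVs bit-identically. The recovery experiments in
`dentinemp.experiments` use the full study geometry (9 specimens × 5
regions at 512 px) and complete in well under a minute; unit tests use
90 µm / 256 px fields, which keep every pixel-limited bound identical
(the pixel size is unchanged) at a quarter of the cost.

## Known limitations

- The width estimator measures the stripe period; comparisons with
  transversal lumen diameters from electron microscopy are interpretive.
- Pixel-limited width accuracy (±1 px) translates into a small wobble of
  recovered regression slopes; tolerances in the acceptance experiments
  reflect this.
- ρ inversion assumes cylindrical symmetry, co-registration, and a
  per-region single fiber orientation; mirror-degenerate orientations are
  rejected rather than resolved (see above).
- INAG depends on relative detector gains of the two channels; the index
  is gain-ratio-calibrated only in the sense that both channels share one
  synthetic detector model. Absolute radiometric calibration is out of
  scope.
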