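# Methods

This note records the models, numerical choices and limitations behind
`pelkit`, in the order data flows through the package.

## Physical setting

Polarization-gated laparoscopy illuminates tissue with linearly
polarized white light and records co- and cross-polarized reflectance
frames. Light scattered only in the superficial layer largely keeps its
incident polarization (co channel); multiply-scattered deep light
returns depolarized and splits evenly between the channels. The frame
algebra is therefore

    WLL = I_co + I_cross            (surface + deep, the white-light image)
    PEL = I_co - I_cross            (surface only, the polarization-gated image)

summed over the R, G, B channels. The quantity the imaging chain is
ultimately designed to sense is the *scattering power* b, the exponent
of the reduced scattering spectrum mu_s'(lambda) ~ lambda^-b. It is
inversely related to the effective scatterer cross section, and rises
in malignant tissue where fine, sparse, aligned collagen replaces the
coarser benign matrix. mPEL is a linear surrogate for b built from the
three RGB differentials.

## Mie optics

Spheres of index 1.42 in a 1.35 medium; the series is summed to the
Wiscombe order (x + 4x^(1/3) + 2) with Riccati-Bessel functions from
scipy's spherical Bessel routines, valid for the real indices and size
parameters (x <= ~40) used here. The angular grid holds 1801 samples on
[0, pi] (phase-function quadrature error < 0.1% for x <= 30). The
radius for a requested cross section is inverted by bisection on the
first monotone branch of sigma_sca(r), which makes the inverse unique;
cross sections above the first Mie resonance maximum are rejected with
the attainable range in the error message.

## Tissue model

Absorption is oxygenated hemoglobin at 15 g/dL whole-blood
concentration diluted by the blood volume fraction:
mu_a = bvf ln(10) eps(lambda) C_molar with C_molar = 150 g/L / 64500
g/mol. The packaged extinction table is a smooth parametric
reconstruction (Gaussian Soret and Q bands at the textbook positions
and magnitudes) rather than a measured compilation — it is labelled
synthetic, and only its band structure matters downstream. Oxygen
saturation defaults to 1.0 and is configurable; no other chromophores
are modelled.

Scattering comes from a monodisperse sphere suspension. The sphere
radius is set by the target cross section at the 550 nm mid-band
reference; the number density is set so the *Mie-consistent* reduced
coefficient rho sigma(lambda) (1 - g_Mie(lambda)) matches the requested
mu_s' at 550 nm. Anchoring the reduced (transport) coefficient rather
than mu_s itself is what makes the total white-light reflectance a
function of mu_s' alone — by the similarity relation, slabs with equal
mu_s' look alike in WLL regardless of sphere size, and scattering-power
contrast appears only in the polarized channels. (Scaling mu_s with a
fixed g = 0.9 while the phase function carries the sphere's own
g ≈ 0.96-0.99 was tried first and makes WLL vary by ~30% across sphere
sizes, contradicting the intended behaviour.)

Two conventions deliberately use the fixed transport anisotropy
g = 0.9 instead of the wavelength-dependent Mie g:

* the slab thickness: D = tau / (mu_a + mu_s'/(1-0.9)) at 550 nm with
  tau = 20, so all conditions with equal mu_s' share one geometry;
* the scattering-power label b, fit on the cross-section spectrum shape
  (equivalently mu_s'/(1-0.9)). The Mie-consistent reduced spectrum
  includes the wavelength dependence of g, which nearly cancels the
  cross-section slope and would compress b to a ~0.07-wide band; the
  fixed-g convention spans b ≈ 1.48-1.93 over the cross-section grid,
  the contrast range the regression is meant to resolve.

The simulation grid reads "10-35 cm^-1 in 5 equal steps" as the six
values {10, 15, 20, 25, 30, 35}; cross sections run 0.5-8 um^2 in 0.5
steps (16 values) and blood volume fractions 0.4-0.9% in 0.1% steps.

## Polarized Monte Carlo

Photon packets carry position, direction, a statistical weight and a
Stokes vector referenced to a local orthonormal frame. Free paths are
exponential in mu_t; at each interaction the weight is multiplied by
the albedo (the absorbed share is tallied), and packets below 1e-4
weight play Russian roulette with survival 0.1. Scattering angles are
sampled from m11(theta) I + m12(theta)(Q cos 2phi + U sin 2phi) by
composition (theta from an inverse-CDF table of m11 sin theta, phi
uniform) and rejection with acceptance probability
(1 + (m12/m11)(Q cos 2phi + U sin 2phi)/I)/2, which is bounded in
[0, 1] because |m12| <= m11 and the Stokes vector is physical. The
Stokes update rotates into the scattering plane, applies the sphere
Mueller matrix, and renormalizes I to 1 (energy lives in the weight);
the sampling density equals the post-rotation intensity, so the
renormalization is unbiased.

Boundaries use the unpolarized average of the s/p Fresnel reflectances
(a full polarized Fresnel treatment is out of scope); a matched-boundary
mode exists for closed-form checks. The specular reflection of the
incident beam (2.2% at normal incidence) is tallied separately from the
diffuse co/cross channels and included in the energy budget. All
photons exiting the top surface are detected regardless of angle (no
aperture cut); at exit the Stokes vector is rotated so its reference
axis aligns with the projection of the lab x axis transverse to the
exit direction, and the packet contributes w(I+Q)/2I to co and
w(I-Q)/2I to cross.

Each grid point of a lookup-table build gets its own seed (base seed +
point index, recorded per row), so the table is reproducible and
independent of execution order.

### Monodisperse resonance ripple

Because every grid point is a single sphere size, the polarized
backscatter carries Mie resonance structure: between closely spaced
sphere sizes the PEL value can ripple non-monotonically even though the
broad trend over b is clearly monotone. Trend properties are therefore
asserted across well-separated scattering powers (cross sections 0.5,
1, 2, 8 um^2), and the lookup tables average over 13 wavelengths per
band to smooth the ripple. A polydisperse size distribution would
remove it entirely but is out of scope.

### Problem sizes

The packaged lookup table (63 conditions x 13 wavelengths, 10k photons
per simulation, seeds recorded) is built once by
`scripts/build_packaged_lut.py` with the same engine; the test suite
rebuilds a reduced table (4 conditions x 13 wavelengths, 6k photons)
live to exercise the full chain, and uses the packaged table where a
63-point build would be disproportionate (the regression sign-pattern
check and phantom rendering). Statistical tolerances in the tests are
3/sqrt(n) for energy balances and binomial 3-sigma for rates.

## Detector model and mPEL

RGB values are quantum-efficiency-weighted integrals of the reflectance
spectra over 350-750 nm. The real camera's curves are unpublished, so
the default response is a tri-Gaussian model (peaks 460/530/600 nm,
80 nm FWHM, equal peak height, equal areas within 1%) and the
illuminant defaults to flat white; both are replaceable via CSV.
Coefficients re-fitted on this package's lookup table therefore cannot
numerically equal the published device set
{0.4705, -0.0073, -0.0039, +0.1104} (shipped in
`mpel_coefficients_published.json` with provenance "published").

The fitted and published sets in fact differ qualitatively, and the
difference is diagnostic of the model. The device set is blue-dominant
with a negative red weight — a color-slope reading, where a
steeper-than-red blue differential signals high scattering power. On
this package's lookup table the OLS optimum weights all three channels
*positively* (R^2 ~ 0.5): each channel differential individually rank-
correlates with b at rho 0.5-0.6, the channels are strongly collinear,
and the pure color feature (dB - dR)/(dB + dR) carries almost no b
information (Spearman ~ 0.2). Two model properties explain this.
First, the dominant b mechanism here is amplitude-borne: smaller
(higher-b) spheres depolarize less per event, raising the polarized
differential in *every* channel together. Second, the color-slope
mechanism is suppressed because for monodisperse Mie spheres in this
size range the wavelength dependence of the anisotropy nearly cancels
the cross-section slope, leaving the transport reduced-scattering
spectra with exponents of only ~0.35-0.42 across the whole grid —
there is little spectral-slope contrast for the colors to read.
Per-sphere resonance ripple further decorrelates color from b. A
polydisperse scatterer population, whose reduced-scattering slope
survives in transport, would be required to recover a blue-dominant
fit; that is out of scope, and the package reports the fit its own
physics produces rather than emulating the published pattern.

The regression is ordinary least squares of b on (dR, dG, dB) with an
intercept, no regularization or interactions, reporting R^2 and
coefficient standard errors; rank-deficient designs are rejected with
the collinear columns named. For image application the frames are
normalized from their digital-number range ([0, 4095] at 12 bits) to
the [0, 1] reflectance-fraction scale the fit was made on, and the
resulting raster is contrast-adjusted by saturating the bottom and top
1% of pixels.

## Frame pre-processing and glare exclusion

Each frame is converted from linear RGB to Lab (sRGB primaries, D65
white point, applied to linear intensities without display gamma since
camera counts are linear). On L only: Gaussian denoising (sigma
0.5 px), homomorphic illumination correction (log-transform, subtract a
sigma-15 px Gaussian low-pass, restore the global log-mean,
exponentiate — a flat field passes through unchanged), and 1%/1%
percentile saturation; a and b are untouched. All convolutions use
reflect padding. Glare candidates are pixels at or above the co frame's
99.5th luminance percentile *and* at or below the cross frame's 0.5th
percentile — specular highlights are bright in co and dark in cross,
the opposite of tissue. Candidate regions are delimited with Canny
edges (automatic hysteresis), filled, dilated by 2 px to catch halos,
and excluded from every downstream statistic. The mask is computed on
the raw frame pair (glare is an acquisition artifact, not a property of
processed intensities). The per-frame processing is exclusion-aware:
excluded pixels are inpainted by normalized convolution at the
illumination scale before the log low-pass, and the saturation
percentiles are taken over valid pixels only — otherwise a bright
glare blob would bend the global illumination estimate and shift the
processed statistics of the whole frame, defeating the point of the
exclusion. Co/cross temporal misregistration is not
corrected — no algorithm is defined for it — but the phantom generator
can inject sub-pixel offsets to measure sensitivity.

## ROI statistics

Lesion ROIs are label rasters; the background for Weber contrast
C_W = (I_f - I_b)/I_b is every valid pixel outside *all* ROIs (other
lesions never contaminate the background). Modalities are compared by
one-way ANOVA with Tukey HSD post-hoc tests, class contrasts by
pooled-variance two-sample t-tests (Welch by flag), and 2x2 detection
counts by the two-sided Fisher exact test with the point-probability
definition of two-sidedness. Degenerate inputs follow stated
conventions: identical constant groups give p = 1.

## Collagen directional variance

Fibers are segmented by Otsu's threshold (256 bins). Local axial
orientation comes from the gradient structure tensor, combined as an
intensity-weighted vector sum of doubled angles over a 5 px window with
0.8 px gradient smoothing — deliberately the scale of a single fiber
width. Calibration on synthetic von Mises fiber fields showed that a
33 px orientation window pools neighbouring fibers toward the local
mean and biases the recovered variance low by 0.15-0.3, while the
single-fiber scale recovers the analytic circular variance within
+-0.05 for concentrations kappa in {0.5, 2, 8}; the residual positive
bias (~0.04 at high kappa) is orientation-estimation noise. The
localized variance *map* is then evaluated over 33 px neighbourhoods,
and ROI summaries use the circular variance of doubled angles,
1 - |mean exp(2i theta)|, over fiber pixels (length-weighted, since
every fiber pixel counts). Z-stacks are maximum-intensity projected.

## Synthetic phantoms

Phantoms place elliptical lesions with higher scattering power (smaller
spheres) on a lower-b background; per-pixel co/cross RGB values come
from the lookup table, so phantom optics inherit the Monte Carlo
physics. A uniform depolarized deep-tissue term (default 60% of the
background co level) is added equally to both frames — it cancels in
PEL, which is exactly why polarization gating raises lesion contrast. A
radial vignette multiplies both frames, glare ellipses saturate co and
floor cross, and noise is Poisson at a 10,000-electron full well mapped
to 12 bits plus 2 DN Gaussian read noise. Everything is deterministic
per seed.

What the phantoms do *not* emulate: organ geometry and shading, specular
sheen away from glare cores, motion and temporal misregistration
artifacts (beyond an optional rigid offset), spatially varying blood
content, and the mixed scatterer populations of real tissue. Passing
phantom tests therefore demonstrates that the chain recovers the
physics it models — not clinical performance; the printed clinical
effect sizes (fold-changes, group means) depend on patient imagery that
is not reproducible here, and only the directions of those effects are
asserted on phantoms.

## Known limitations

* Monodisperse spheres: Mie resonance ripple (above); no size
  distributions, coated or non-spherical scatterers.
* Unpolarized-average Fresnel boundaries; no polarized specular model.
* Single homogeneous layer; no layered or laterally heterogeneous
  optics beyond the phantom's piecewise-constant maps.
* The detector and illuminant are models, so absolute mPEL coefficient
  values are detector-relative.
* The hemoglobin table is a labelled synthetic reconstruction, adequate
  for band structure, not for spectroscopy.
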