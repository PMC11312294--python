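# Methods

## Colorimetric conventions

All spectral quantities live on a uniform 1 nm grid from 380 to 780 nm
(401 samples); tabulated curves are linearly interpolated onto it. The
observer is the CIE 1931 2° standard observer and the illuminant is D65,
both shipped as 10 nm tables. Neither choice is forced by the conversion
method itself, but sRGB is defined for D65 and the 2° observer, so any other
pairing would make the fixed sRGB↔XYZ matrix inconsistent with the spectral
integration. Tristimulus values use the Y(white) = 100 convention: the
spectrum-to-XYZ integral is normalized so a perfect reflector has Y = 100,
which puts a near-white chart patch in the high 80s–90s, matching the scale
of published chart-calibration tables. With these tables the integrated
white point lands at chromaticity (0.3129, 0.3293), within 0.001 of nominal
D65.

The sRGB transfer function is the exact piecewise standard (linear toe below
0.04045 / 12.92, exponent 2.4 above), not a bare 2.2 power law: the camera
simulation and the decode path must invert each other exactly for the
identity-distortion case to close, and the piecewise form is the one 8-bit
sRGB files actually use. CIEDE2000 is implemented in full (a*-rescaling G
term, lightness/chroma/hue weights, blue-region rotation term, parametric
factors 1); the test suite checks it against an independent implementation
(scikit-image) on random and published verification pairs to 1e-4.

## Camera correction

The feature expansion is the 11-term set
[1, X, Y, Z, XY, XZ, YZ, X², Y², Z², XYZ]. Rationale: the constant absorbs
dark current, the linear block absorbs crosstalk and color shift, and the
quadratic + cross terms absorb smooth nonlinearity such as a mis-set gamma.
The term list is configurable (any monomial string over X, Y, Z, constant
first) but must not exceed the 24 patches available to fit it. The fit is an
ordinary least-squares pseudo-inverse (SVD, relative singular-value cutoff
1e-10); a rank-deficient chart produces a warning, not an error, because the
minimum-norm solution is still well defined.

The calibration report's per-patch RMSE is the root-mean-square difference
of the camera-side and corrected XYZ triplets, sqrt(((ΔX)²+(ΔY)²+(ΔZ)²)/3).
Note that when such a table is printed with triplets rounded to 2 d.p., the
recomputed RMSE can differ from a value computed on unrounded data by up to
one unit in the final digit; the embedded reference table shows exactly this
on 4 of 24 rows. Its SD column is carried but not validated — no standard
deviation definition reproduces it from the printed triplets.

## Spectral basis and reconstruction

PCA of the 24 chart reflectances is mean-centered (the mean spectrum is
stored and restored at reconstruction); centering makes the explained-
variance ratios meaningful and keeps the eigenvectors orthonormal. K
defaults to 6 components, configurable up to the rank of the training set.
Scores are regressed on the feature expansion of the *corrected* XYZ — the
corrected colors, not the raw camera colors, are what the basis should be
predicted from, since correction is applied before reconstruction at
inference time. Reconstructed spectra are clipped to [0, 1.2]: negative
reflectance is unphysical, and the 20 % headroom tolerates mild specular
overshoot on extrapolated bright colors.

Image conversion memoizes on unique 8-bit RGB triplets. The memoized path is
bit-identical to evaluating every pixel (same arithmetic per color, verified
in the tests), and for natural 8-bit images it cuts the work by orders of
magnitude.

## Narrow bands and pseudo-color

Bands default to centers 415, 540, 600, 700, 780 nm. Widths: 30 nm FWHM at
415 nm and 20 nm at 540 nm (the conventional hemoglobin-band widths of
narrow-band endoscopy), 20 nm for the three longer "realism" bands. The
kernel is Gaussian rather than boxcar for smoothness on the 1 nm grid, with
weights normalized to sum to one; an FWHM below the grid step degenerates to
nearest-slice sampling.

The band-to-display mapping is affine (3×B weights + offset). When reference
patch colors exist it is fitted by minimizing mean CIEDE2000: a linear
least-squares warm start in display-linear RGB (a perceptually reasonable
linearization of the objective) followed by Nelder–Mead refinement of the
true ΔE₀₀ objective, accepted only if it does not increase the objective —
so the fit is deterministic and never worse than the warm start. Without
references, a cosmetic default mapping renders short-wavelength content
bluish-cyan and long-wavelength content warm brown, echoing the familiar
narrow-band endoscopy palette; it makes no accuracy claim.

## Synthetic fixtures: what they emulate and what they do not

Measured chart reflectances are not redistributable here, so the fixture
chart is synthetic: each patch is a clipped linear combination of nine
smooth primitives (Gaussian bands around 435/465/545 nm, cut-on sigmoids at
510/565/605 nm, a short-pass edge at 590 nm, a near-infrared upturn, and a
flat term). This mimics how physical charts are painted from a limited
pigment palette, and it is that shared palette that gives the 24 spectra
their low effective dimensionality (6 components ≈ 99.97 % of variance,
versus ≈ 99.6 % typically reported for measured charts). Layout follows the
classic chart: chromatic primaries at positions 13–18, white at 19, greys
descending to black at 24, all verified in-gamut under D65.

The synthetic camera applies, in linear RGB: a 3×3 crosstalk matrix, a
per-channel dark offset, a per-channel exponent perturbation v → v^(1+g),
and seeded additive Gaussian noise, then re-encodes and is decoded by an
ideal sRGB observer. Defaults: crosstalk I ± 0.05 off-diagonals, dark offset
0.02, gamma error (+0.1, −0.1, +0.1), noise SD 0.002, seed 1672 — a
plausibly miscalibrated consumer camera. Encoding uses a sign-symmetric
extension of the sRGB curve so the chain stays exactly invertible for
slightly out-of-range values.

The lesion generator renders a light-skin background spectrum attenuated
inside an ellipse by a melanin-like absorbance ∝ (500/λ)³, so the lesion is
darkest at short wavelengths by construction — which is what makes the
415 nm band check meaningful, and also why it proves nothing about real
melanin spectra.

What passing tests therefore show: the *fitting machinery* recovers known
distortions and known low-dimensional spectra to the stated tolerances.
What they do not show: performance on real cameras (whose distortions are
not polynomial), real charts (whose spectra are less exactly
low-dimensional), or real skin (whose optics include scattering this model
omits). Quantities published for hardware pipelines (spectrometer-measured
RMSE values, detector mAP tables, comparisons against endoscope reference
frames) are consequently treated as tolerance-based properties on the
synthetic loop, not as equalities.

## Problem sizes and runtime

All training uses the 24-patch chart; demonstration images are 24–64 px
square (the conversion is per-pixel and memoized, so image size only scales
the scatter step). The full test suite runs in a few seconds; the
acceptance script in about one.

## Known limitations

- Single-illuminant design: no chromatic adaptation between capture and
  reference illuminants.
- The polynomial correction extrapolates poorly outside the chart gamut;
  corrected XYZ of saturated colors can overshoot before clipping.
- Five narrow bands cannot reproduce arbitrary full-spectrum colors; the
  fitted NBI mapping typically leaves a residual mean ΔE₀₀ of ≈ 2 on the
  chart, which is inherent to the band bottleneck, not the optimizer.
- The analog spectrum of a color never seen near the training chart's span
  is a low-dimensional guess; K = 6 components cannot represent spiky
  spectra (e.g., discharge-lamp illumination).
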