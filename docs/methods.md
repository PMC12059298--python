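# Methods

## The measurement model

The package treats a CT sequence as repeated noisy observations of one
edge. Each axial slice shows a high-attenuation object (PMMA phantom or
patient body, ≥ 0 HU) on an air background (≈ −1000 HU). The image is
modeled as the object indicator convolved with the scanner's in-plane point
spread function (PSF), sampled on the pixel grid and corrupted by noise.
The modulation transfer function (MTF) — the modulus of the PSF's Fourier
transform normalized to 1 at zero frequency — is estimated from the edge
spread function (ESF) across the top object/air boundary.

Assumptions:

* the boundary is locally straight and horizontal across the 41-pixel ROI
  (the ROI sits at the top of the object, where the boundary tangent is
  horizontal by construction; residual curvature biases the column-averaged
  ESF slightly toward lower resolution and is accepted);
* in-plane pixels are square (anisotropic spacing is rejected on read);
* the PSF is shift-invariant over the ROI and constant along the sequence;
* HU values are what the scanner reconstructed — no beam-hardening or
  motion model.

## Pipeline and parameters

Per slice: threshold segmentation (default **−500 HU**, midway between air
and tissue; configurable) → largest 4-connected component, holes filled →
centroid → first foreground pixel walking down the centroid column → ROI of
(2h+1)² pixels, default **h = 20** (41×41, the size used in single-image
edge QA at typical chest FOVs) → column-average ESF (positions in mm, air
side first) → cubic-spline upsampling ×**5** → central-difference LSF →
baseline zeroing (mean of the first five, air-side samples) → sign fix →
range normalization → FFT magnitude, normalized to 1 at DC and truncated at
the **original** Nyquist frequency 1/(2·pixel spacing): spline upsampling
creates no information beyond it, it only refines the frequency grid.

Per sequence: the per-slice 41-point ESFs (aligned by construction — each
ROI is centered on its detected edge) are pooled and fitted with a cubic
smoothing spline; the penalty is chosen by **generalized cross-validation**
by default. A user-supplied smoothing parameter p ∈ (0, 1] follows the
csaps convention (penalty λ = (1−p)/p, p = 1 interpolates). Replicated
positions are collapsed to weighted means before fitting, which is the
exact weighted-least-squares equivalence; when the replicates are exactly
degenerate (noiseless input) GCV's optimum is interpolation and an
interpolating spline is used directly. The pooled smooth curve is evaluated
on the ×5 grid and sent through the same LSF → MTF chain.

Metrics: 50%MTF and 10%MTF are the frequencies of the *first downward*
crossings of 0.5 and 0.1, linearly interpolated between bracketing samples
(first crossing, because noisy tails can re-cross). In pooled mode a
four-parameter Gaussian + Lorentzian model

MTF_fit(f) = [c·exp(−π²f²/d) + a/(1 + 4π²f²b²)] / (c + a)

is fitted by bounded least squares (multi-start; f in lp/cm) and metrics
are read off the model on a 0.01 lp/cm grid. The (a, c) pair only enters
through its ratio, so fits are normalized to a + c = 1. The printed source
formula for this model circulates in several typographically corrupted
variants; the form above is the one whose value at f = 0 is exactly 1,
which is the binding normalization contract. It is a configuration point,
not a physical claim.

## Numerical choices

**Sampling-chain response compensation.** Interpolating a coarsely sampled
ESF and differentiating it numerically attenuates the spectrum by a known,
deterministic amplitude response: cardinal cubic-spline interpolation of
samples spaced T contributes sinc⁴(fT)·6/(4+2cos 2πfT), and the central
difference on the fine grid (spacing Δ = T/5) contributes sinc-like
sin(2πfΔ)/(2πfΔ). At 0.5 mm pixels this is a 7% loss at 0.63 cycles/mm and
54% at Nyquist — far from negligible. The measurement pipeline divides this
response out (config `correct_sampling`, on by default), the MTF analogue
of the standard finite-difference/aperture corrections in edge-method
practice. The bare `lsf_to_mtf` function leaves the correction off unless
asked, so its output is the plain normalized FFT magnitude.

**Model-fit band.** Near Nyquist the corrected curve is dominated by
sampling-alias leakage (at Nyquist the signal and its alias replica
coincide), so the model is fitted only to frequencies up to
`fit_band_fraction` (default **0.6**) of Nyquist. Because the fitted model
is parametric it can be followed moderately past the band; metrics are
evaluated up to twice the Nyquist frequency. That is what makes a 10%
crossing just beyond Nyquist readable (e.g. σ = 0.3 mm at 0.5 mm pixels
puts f10 at 11.4 lp/cm against a 10 lp/cm Nyquist); raw-curve mode keeps
the hard Nyquist cutoff and raises an error instead.

**Degenerate inputs.** A flat ESF (no edge) fails with a specific error
after zeroing, as does an all-zero LSF; a single-curve "pool" returns the
curve unchanged with a `degenerate` flag; slices that fail localization or
metric extraction are skipped with a logged reason, and their ESFs still
feed the pooled fit when only the metric stage failed. Ties when rounding
the centroid column are broken half-away-from-zero.

## The synthetic phantom

`synthetic_phantom` renders a circle or ellipse of +120 HU (PMMA-like) on
−1000 HU air, blurred by an isotropic Gaussian PSF of width σ (mm), with
white Gaussian noise and integer-HU quantization, as CT DICOM stores.
The Gaussian PSF is chosen because its ESF/LSF/MTF are closed-form, giving
an exact oracle: MTF(f) = exp(−2π²σ²f²), f50 = √(ln 2/2π²σ²)·10 lp/cm,
f10 = √(ln 10/2π²σ²)·10 lp/cm.

Rendering evaluates a first-order signed-distance coverage of the boundary
on a 9× supersampled grid, blurs at the fine scale, and **decimates at the
pixel centers**. Reconstructed CT pixels are point samples of a
band-limited function, so decimation — not averaging the fine samples into
the pixel footprint — is the faithful model; footprint averaging would add
a 1-pixel box aperture that belongs to neither the scanner model nor the
closed forms above. With σ = 0 the fine samples are averaged instead
(coverage anti-aliasing of a hard edge).

The default geometry is a flattened ellipse, semi-axes 45 × 115 mm on a
512×512 / 0.5 mm grid, emulating the nearly flat anterior chest wall; its
top-edge curvature radius (≈ 294 mm) keeps the curvature bias of the
column-averaged ESF well below the oracle tolerances. Sequences drift the
radii linearly (anatomy changing along z) and seed each slice's noise as
`seed + slice_index`.

What the generator does **not** emulate: correlated (kernel-shaped) CT
noise texture, reconstruction-kernel PSFs (which are not Gaussian and can
ring), beam hardening, motion, or anatomy other than one convex boundary.
Passing the synthetic oracles therefore shows the measurement chain is
correct and stable under white noise at a known edge; it does not certify
accuracy on clinical reconstructions with structured noise.

## Problem sizes and determinism

The validation suite measures 20-slice sequences (the slice count analyzed
per sequence in routine use), uses σ ∈ {0.3, 0.5, 0.8} mm at 0.5 mm pixels
for the noiseless oracles, and runs 50 independent noisy sequences
(σ = 0.5 mm, noise 15 HU) for the pooling-stability comparison — enough to
estimate the two standard deviations whose ordering is the claim under
test. All randomness flows through explicit integer seeds; repeated runs
are bit-identical, and DICOM output derives its UIDs from content so writes
are byte-reproducible.

## Known limitations

* The alias contamination near Nyquist is irreducible for a single fixed
  edge phase; sub-pixel (slanted-edge style) binning is deliberately out of
  scope, so very sharp PSFs (σ well below the pixel pitch) are measured
  with reduced margin.
* The smoothing-spline response is slightly stronger than the interpolation
  response the sampling correction assumes; with heavy smoothing (tiny p)
  the pooled MTF is mildly over-attenuated.
* Boundary curvature is not de-tilted; strongly curved objects (small
  phantoms) bias the ESF toward lower resolution.
* Only single-frame DICOM series are supported (no enhanced multi-frame,
  no PACS access).
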