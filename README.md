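# ctseqmtf

Spatial-resolution measurement for clinical chest CT **sequence** images.

Routine CT quality assurance reads the modulation transfer function (MTF)
off phantom scans, but phantoms are static and homogeneous and do not show
what a clinical image actually resolves. `ctseqmtf` measures the MTF
directly from a CT series, using the sharp object/air boundary (a phantom
edge, or the patient's skin) that every chest slice already contains — and
it pools the evidence from *all* slices of the sequence into one stable
estimate instead of trusting a single noisy image.

The package is aimed at medical physicists and QA tool developers: it reads
ordinary single-frame DICOM series, needs no markers or templates, and
ships a synthetic edge-phantom generator with closed-form ground truth so
the whole chain can be validated without scanner time.

## Method

For each slice, the object is segmented by thresholding (default −500 HU),
its centroid $(x_a, y_b) = \bigl(\tfrac1N\sum_n x_n,\ \tfrac1N\sum_n y_n\bigr)$
is computed over the $N$ object pixels, and the point where the vertical
centroid line meets the top object boundary becomes the center $(x_c, y_c)$
of a 41×41-pixel ROI. Averaging the ROI across columns gives the edge
spread function (ESF); cubic-spline upsampling (5×), differentiation to the
line spread function (LSF), zeroing against the air-side tail and range
normalization, and a Fourier transform yield the per-slice MTF.

For the sequence-level result, the per-slice ESF samples are pooled into
one scatter and fitted with a smoothing spline (penalty chosen by
generalized cross-validation), producing a single sequence ESF → LSF → MTF.
Optionally the MTF is stabilized with a four-parameter model,

$$\mathrm{MTF}_{fit}(f) = \frac{c\,e^{-\pi^2 f^2/d} + \dfrac{a}{1+4\pi^2 f^2 b^2}}{c+a},$$

and the headline metrics are the frequencies where the MTF first falls to
50% and 10%, reported in lp/cm (1 cycle/mm = 10 lp/cm). The measurement
pipeline also divides out the known amplitude response of its own
interpolation/differentiation chain; see `docs/methods.md` for the
numerical details and assumptions.

## Worked example

Simulate a 40-slice phantom sequence with a Gaussian point-spread function
of σ = 0.5 mm and 15 HU of noise, then measure the slices 16–35 as one
sequence:

```console
$ ctseqmtf simulate --out demo --sigma-mm 0.5 --slices 40 --noise-sd 15 --seed 42
wrote 40 slices to demo
$ ctseqmtf measure --input demo --slices 16:35 --out demo_result
processed 20 of 20 slices
pooled 50%MTF = 3.87 lp/cm, 10%MTF = 7.05 lp/cm
wrote demo_result.json and demo_result_curve.csv
```

A Gaussian PSF of σ = 0.5 mm has the closed-form values
f50 = √(ln 2 / 2π²σ²)·10 = 3.75 lp/cm and f10 = √(ln 10 / 2π²σ²)·10 =
6.83 lp/cm, so the pooled estimate above lands within a few percent of
truth despite the noise; `demo/truth.json` records the analytic values.
`demo_result.json` holds the pooled and per-slice metrics plus the full
configuration; `demo_result_curve.csv` holds the MTF curve
(`frequency_lp_per_cm, mtf_raw, mtf_fitted`).

The same pipeline is available as a library:

```python
from ctseqmtf import PhantomSpec, generate_sequence, measure_sequence

series = generate_sequence(PhantomSpec(psf_sigma_mm=0.5), n_slices=20)
result = measure_sequence(series)
print(result.pooled.f50_lp_per_cm, result.pooled.f10_lp_per_cm)
```

`ctseqmtf validate` prints the comparison statistics over the packaged
20-slice table of paired single-image measurements (the proposed
single-image method vs the IndoQCT QC program, by tube current), e.g. a
Pearson correlation of 0.86 between the two methods' 50%MTF values.

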