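# Methods

This note records the models, parameter choices and numerical conventions
behind `deepfascia`, and what the synthetic-phantom experiments do and do
not demonstrate.

## Signal model and subtraction contrast

Each tissue is modelled as mono-exponential in echo time,
S(TE) = S0·exp(−TE/T2*). The default tissue parameters are

| tissue | S0 | T2* (ms) |
|--------|-----|---------|
| muscle | 1.0 | 25 |
| fat | 0.9 | 15 |
| fascia | 0.8 | 1.2 |
| bone | 0.3 | 0.4 |
| background | 0 | — |

These are plausible-contrast placeholders, not scanner calibrations: they
reproduce the ordering the dual-echo method relies on (fascia and cortical
bone bright only at ultra-short TE; muscle and fat persisting to the second
echo). Default echo times are 0.05 and 5.19 ms. At these settings fascia
retains 96% of its signal at TE₁ and 1.3% at TE₂, while muscle loses only
19% between echoes.

Region-specific scaling multiplies the **UTE** echo (the lower-SNR image,
scaled *up* into the second echo's intensity regime) by
f = median(shTE|ROI)/median(UTE|ROI) over a non-target ROI. The ROI
defaults to an automatic muscle estimate: the largest connected component
of short-TE pixels within ±20% of the foreground median, eroded 3 px.
Muscle is chosen because it is the dominant tissue surrounding fascia, so
cancelling it maximises local contrast. The median is the primary statistic
(robust to the skew a bias field or the fascia ring itself induces); if the
mean- and median-ratios disagree by more than 20% the two are averaged and
the result is flagged "blended". After median-ratio scaling the ROI median
ratio equals 1 to 1e-6 by construction, and this is asserted at run time.

Because the bias field multiplies both echoes identically, the scaled
subtraction cancels a biased non-target tissue *exactly* up to noise,
whereas naive subtraction leaves a bias-modulated muscle residual. This is
why the SNR experiments enable the bias field: it is the regime in which
scaling matters. SNR is defined as mean(signal ROI)/std(background ROI);
the phantom experiments use fascia truth as the signal ROI and muscle truth
as the background ROI, since muscle residual is precisely what the scaling
step is designed to remove. The subtraction is clipped at zero (negative
residuals carry no connective-tissue information) and min–max normalised so
the downstream absolute threshold (0.6) and clustering operate on [0, 1].

## Phantom

The phantom renders a lower-leg axial cross-section as concentric
compartments on a 256² grid at 0.5 mm/px: leg radius 55 mm, subcutaneous
fat 8 mm, deep-fascia annulus 1.5 mm (optionally a function of polar
angle), bone radius 10 mm, optional aponeurosis-like septum through the
muscle. Pixels are classified radially at their centres with no
anti-aliasing, which makes the ground-truth masks and thickness exact in
pixel units at the cost of staircased boundaries. Corruptions:

- **Rician noise**, the magnitude of (signal + complex Gaussian), applied
  independently per echo; default σ = 0.02 of muscle S0 (SNR ≈ 40–50 in
  muscle at the second echo — an optimistic but realistic 3T level).
- **Periodic interference**: an additive sinusoid specified by (amplitude,
  cycles/image, orientation). Its phase is drawn independently per echo:
  identical stripes on both echoes would cancel identically in the
  subtraction, which is not how interference behaves across separate
  readouts. With random phases, the stripe residual in the subtraction
  varies between realisations (occasionally the phases nearly cancel); the
  corruption experiments therefore fix seeds where stripes survive.
- **Bias field**: exp(2-D polynomial in coordinates normalised to [−1,1]),
  normalised to mean 1 — multiplicative, smooth and identical across
  echoes.

The stripe-corruption scenario used for evaluating the FFT stage is
amplitude 0.2, 32 cycles/image, 30°: a pilot sweep showed 0.2 is the
smallest amplitude at which the interference actually defeats uncorrected
intensity clustering (at 0.1 the uncorrected route is still essentially
perfect and a comparison is uninformative).

What the phantom does **not** emulate: partial-volume edges, fat–water
chemical shift, coil-array noise correlation, motion, anatomy beyond
concentric geometry, or registration error between echoes (they are
rendered co-registered, as in a dual-echo acquisition). Passing the
phantom tests therefore demonstrates algorithmic correctness and the
contrast mechanism, not clinical performance.

## Enhancement

- `contrast_adjust` remaps [mean − 2σ, mean + 2σ] ∩ observed range linearly
  to [0, 1]; ±2σ covers ~95% of a Gaussian intensity histogram. Constant
  images are rescaled by their maximum with a warning.
- `top_hat` is a white top-hat with a radius-10 disk: bright structures
  narrower than the disk (a fascia ring a few pixels wide) survive at full
  contrast; wider ones are removed.
- `wiener_denoise` computes per-pixel local mean μ and variance σ² over a
  20×20 window and returns μ + max(σ²−ν,0)/max(σ²,ν)·(x−μ), with noise
  power ν the mean of the local variances. It is implemented in-package
  with reflective-boundary local statistics: zero-padded implementations
  bias μ at the image border and then fail the basic identity that a
  noiseless constant image passes through unchanged.

## FFT denoising

The centred spectrum's log-magnitude log(1+|F|) is thresholded at
mean + 3.5σ computed *outside* a protected central disk of radius
0.08·min(grid dims); flagged bins and their conjugate mirrors are zeroed
(conjugate symmetry keeps the reconstruction real). An optional Gaussian
low-pass H = exp(−r²/2D0²) with D0 = 0.3·Nyquist follows, and the real
part of the inverse transform is min–max normalised.

Numerical note: the spike mechanism is essentially lossless on
uncorrupted images (zero to a handful of false-positive bins; relative L2
change ≈ 0), while the Gaussian low-pass necessarily attenuates the edge
spectrum of a piecewise-constant image — about 6–8% relative L2 on the
phantom regardless of how the protected disk is handled. Clean-image
fidelity is therefore a property of spike suppression and is tested with
the low-pass disabled; both numbers are reported by the acceptance script.

## Segmentation

K-means runs on the flattened intensities (k = 3 by default — fascia,
muscle/fat residue, background). Each of 10 replicates draws k distinct
observed intensities as initial centroids from a seeded RNG and runs Lloyd
iterations (assignment by sorted-centroid midpoints, convergence at
max-shift < 1e-6 or 300 iterations); the replicate with the lowest
within-cluster sum of squares wins and labels are reported 1..k by
ascending centroid. On tiny inputs the restart strategy occasionally
misses the global optimum (the optimal 1-D 2-means split of sorted data,
found exhaustively, is the oracle in the tests); the acceptance script
reports the observed match fraction. The fascia mask is the brightest
cluster, filtered to connected components that touch a ±3 px band around
the boundary of the largest mid-intensity component (the muscle/fat
interface where deep fascia lies), which rejects bone and noise specks
without closing genuine gaps in the ring.

The watershed binarises at 0.6, negates the Euclidean distance transform
of the foreground, excludes background from flooding, and floods with
8-connectivity; ridge pixels and background are labelled 0. Watershed
region labels are reported with their mean image intensity so a caller
can map regions to tissues.

## Thickness

The mask is thinned to a 1-px skeleton; spur branches are pruned by 5
iterations of endpoint removal (closed annulus midlines have no endpoints
and are untouched). At each skeleton pixel the local tangent comes from a
PCA of skeleton neighbours within radius 3.5 px; rays march along ±normal
in 0.25-px steps and the boundary is located as the subpixel 0.5-level
crossing of the bilinearly interpolated mask. Thickness is the sum of the
two half-distances times the pixel spacing (isotropic in-plane spacing is
required; row/col spacings differing by >1% raise an error).

Summing the two sides rather than doubling the distance-transform value
at the skeleton makes the estimate insensitive to the skeleton sitting
half a pixel off the true midline, which is unavoidable for even-width
structures; the coarser 2·EDT−1 variant is retained as `method="edt"`.
Measured bias on exact-width bars (2–10 px) is zero at 0°/90° to the
sampling step and ≤ 0.7 px at 45°, where the discrete boundary is
staircased. Per-slice means average only slices with a nonempty skeleton;
the overall thickness averages those per-slice means.

## Architecture

Fascicle length is polyline arc length; tracts outside the closed
interval [5, 200] mm are discarded. The fascicle vector is the end-to-end
chord, and pennation is arccos(|chord·loa|/‖chord‖), folded to [0, 90]°
because fiber orientation is direction-agnostic. The line of action, when
not supplied, is the principal eigenvector of the physical-coordinate
covariance of the muscle voxels (sign-fixed to +z); a single-slice mask is
rejected as rank-deficient. PCSA = volume / mean fascicle length holds by
construction and is re-asserted on every report. The pennate generator
places straight tracts whose chords make exactly the requested angle with
the line of action (azimuth uniform), with lengths uniform in the
requested range — so mean-angle recovery to 0.1° and mean-length recovery
against the uniform expectation (102.5 mm for [5, 200]) are exact
parameter-recovery checks.

## Pipeline and problem sizes

`run_pipeline` enforces the stage order subtract → enhance → fft →
{kmeans | watershed} → thickness, writes every intermediate as NIfTI and a
`provenance.json` with all parameters and the seed (sufficient to re-run
the job bit-identically for the deterministic stages). Experiments in the
tests and the acceptance script use the 256² phantom, 20-seed ensembles
for the scaling/SNR statistics, 20 random 16-pixel images for the
clustering oracle, and 1000 tracts for architecture — sizes at which every
quantity is stable to well under its tolerance while the whole suite runs
in seconds.

## Known limitations

- Tissue parameters and corruption levels are stated conditions, not
  scanner calibrations; absolute SNR values on the phantom are not
  comparable to in-vivo figures.
- 2-D slice-wise processing only; no through-plane regularisation.
- The watershed route labels catchment regions but does not by itself
  decide which are fascia; the intensity-statistics mapping is a
  convenience, not a validated classifier.
- Tract generation here is geometric; no diffusion modelling or
  tractography is performed, so architecture results on synthetic tracts
  validate the metrics, not a tracking method.
- DICOM support covers single-frame MR series with uniform pixel spacing;
  multi-frame and multi-orientation series are out of scope.
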