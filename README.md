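# deepfascia

Processing pipeline for **dual-echo ultra-short echo time (UTE) MRI of deep
connective tissue** — deep fascia and aponeurosis in the lower limb — plus
streamline-based muscle-architecture metrics.

## The problem

Collagen-rich tissue has an effective transverse relaxation time T2* of
~1 ms, so it has already lost its signal at conventional echo times and
appears dark. A dual-echo UTE acquisition collects one image at an
ultra-short echo time (TE₁ ≈ 0.05 ms), where fascia is still bright, and a
second at a short conventional echo time (TE₂ ≈ 5 ms), where it is not,
while muscle and fat (T2* ≈ 15–25 ms) barely change. Each tissue decays as

    S(TE) = S0 · exp(−TE / T2*)

Scaling the UTE image by a factor *f* chosen so a **non-target** region
(muscle) matches the second echo — *f* = median(S₂|ROI) / median(S₁|ROI) —
and subtracting,

    D = clip(f·S₁ − S₂, 0) , normalised to [0, 1]

cancels muscle and fat and leaves the thin fascia annulus as the bright
structure. The package implements that contrast mechanism and everything
downstream of it:

- **enhancement**: mean±2σ contrast stretch, white top-hat (disk radius 10),
  locally adaptive Wiener filter (20×20 window);
- **FFT denoising**: periodic interference appears as bright spikes in the
  centred log-magnitude spectrum; bins above mean + 3.5σ (outside a
  protected low-frequency disk) are zeroed with their conjugate mirrors,
  followed by an optional Gaussian low-pass;
- **segmentation**: 1-D intensity K-means (k = 3, 10 replicates, best
  within-cluster sum of squares) and a marker-free watershed of the negated
  Euclidean distance transform of the foreground binarised at 0.6;
- **measurement**: skeleton-midline thickness in mm, Dice/Jaccard overlap
  (J = D/(2−D)), cross-sectional area and volume;
- **architecture**: fascicle lengths, pennation angles against the muscle's
  line of action, and PCSA = volume / mean fascicle length from streamline
  tracts filtered to the 5–200 mm window;
- **phantom**: a synthetic dual-echo lower-leg cross-section (background /
  fat / fascia annulus / muscle / bone, Rician noise, optional stripes and
  bias field) with exact ground truth, so every stage is testable without
  scanner data.

It is intended for musculoskeletal imaging researchers who want a
reproducible, scriptable version of this workflow, or a ground-truthed test
bed for parts of it.

## Worked example

```python
import deepfascia as df

phantom = df.make_phantom(df.PhantomSpec(seed=0))
scaled, scaling = df.region_specific_scale(
    phantom.pair, roi=phantom.truth.binary("muscle")
)
sub = df.subtract(phantom.pair, scaled_ute=scaled)
clusters = df.kmeans_intensity(sub, k=3, replicates=10, seed=0)
mask = df.fascia_mask_from_clusters(clusters, sub)
print(df.dice_jaccard(mask, phantom.truth.binary("fascia")).dice)
thickness, _ = df.skeleton_thickness(mask, phantom.ute.spacing)
print(thickness)
```

Running `python examples/01_phantom_and_subtraction.py` prints:

```
phantom: (256, 256) grid at 0.5 mm/px, echoes at TE = 0.05 / 5.19 ms
scale factor on the UTE echo: 0.8145 (median-ratio)
  mean subtraction intensity over fascia : 0.885
  mean subtraction intensity over muscle : 0.015
  mean subtraction intensity over fat    : 0.138
  mean subtraction intensity over bone   : 0.283
fascia-vs-muscle SNR of the scaled subtraction: 39.8
```

The scale factor matches the muscle medians of the two echoes (the muscle
residual after subtraction is 0.015, versus 0.885 over fascia — the
contrast the dual-echo subtraction exists to create; bone also survives
because cortical bone is itself a short-T2* tissue). The other examples
cover FFT cleanup + segmentation (`02`), thickness measurement (`03`) and
architecture metrics (`04`).

The same stages are available from a shell:

```sh
fascia phantom --seed 0 --out ph/
fascia subtract --ute ph/ute.nii.gz --shte ph/shte.nii.gz --out sub.nii.gz
fascia kmeans sub.nii.gz --seed 0 --out clusters.nii.gz
fascia pipeline --config job.yaml --out run/
```

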