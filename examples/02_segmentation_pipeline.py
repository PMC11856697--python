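"""Segment the fascia on a corrupted phantom: FFT cleanup then K-means.

Adds sinusoidal interference strong enough to defeat plain intensity
clustering, then shows that suppressing the interference spikes in the
frequency domain first restores the segmentation.
"""

import deepfascia as df

phantom = df.make_phantom(
    df.PhantomSpec(seed=7, periodic_noise=(0.2, 32.0, 30.0))
)
truth = phantom.truth.binary("fascia")

scaled, _ = df.region_specific_scale(phantom.pair, roi=phantom.truth.binary("muscle"))
subtraction = df.subtract(phantom.pair, scaled_ute=scaled)

# route 1: K-means directly on the striped subtraction image
clusters = df.kmeans_intensity(subtraction, k=3, replicates=10, seed=0)
mask_plain = df.fascia_mask_from_clusters(clusters, subtraction)
dice_plain = df.dice_jaccard(mask_plain, truth).dice

# route 2: FFT spike suppression first, then K-means
denoised, n_spikes = df.fft_denoise(subtraction)
clusters2 = df.kmeans_intensity(denoised, k=3, replicates=10, seed=0)
mask_fft = df.fascia_mask_from_clusters(clusters2, denoised)
dice_fft = df.dice_jaccard(mask_fft, truth).dice

print(f"suppressed {n_spikes} interference bins in the spectrum")
print(f"Dice vs truth, K-means alone:      {dice_plain:.3f}")
print(f"Dice vs truth, FFT then K-means:   {dice_fft:.3f}")
# Dice near 1 means the segmented annulus overlaps the true fascia almost
# pixel-for-pixel; the uncorrected route mistakes stripe crests for fascia.

thickness_mm, _ = df.skeleton_thickness(mask_fft, phantom.ute.spacing)
print(f"measured fascia thickness {thickness_mm:.2f} mm "
      f"(generator truth {phantom.true_thickness_mm} mm)")
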