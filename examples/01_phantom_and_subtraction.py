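"""Render a dual-echo leg phantom and isolate the fascia by subtraction.

Builds the synthetic lower-leg cross-section, scales the ultra-short-TE
echo so the muscle region matches the short-TE echo, subtracts, and
reports the contrast this produces per tissue.
"""


import deepfascia as df

phantom = df.make_phantom(df.PhantomSpec(seed=0))
print(f"phantom: {phantom.ute.shape} grid at {phantom.ute.spacing[0]} mm/px, "
      f"echoes at TE = {phantom.te1} / {phantom.te2} ms")

muscle = phantom.truth.binary("muscle")
scaled, scaling = df.region_specific_scale(phantom.pair, roi=muscle)
print(f"scale factor on the UTE echo: {scaling.factor:.4f} ({scaling.method})")

subtraction = df.subtract(phantom.pair, scaled_ute=scaled)
for tissue in ("fascia", "muscle", "fat", "bone"):
    mean = subtraction.pixels[phantom.truth.binary(tissue)].mean()
    print(f"  mean subtraction intensity over {tissue:7s}: {mean:.3f}")

# The fascia annulus should carry by far the highest subtraction signal:
# it is the only tissue whose T2* (~1.2 ms) sits between the two echo
# times, so it is bright at TE1 and gone at TE2.
snr = df.measure_snr(subtraction, phantom.truth.binary("fascia"), muscle)
print(f"fascia-vs-muscle SNR of the scaled subtraction: {snr.snr:.1f}")
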