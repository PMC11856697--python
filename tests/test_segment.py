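"""Segmentation phase: FFT denoise, edge map, K-means, watershed, fascia mask."""

import math

import numpy as np
import pytest

import deepfascia as df
from deepfascia.core import SliceImage
from deepfascia.segment import FrequencyFilterSpec


def _img(arr, spacing=(1.0, 1.0)):
    return SliceImage(np.asarray(arr, dtype=float), spacing=spacing)


def _stripe_power(pixels, cycles, orient_deg):
    """Energy in a 3x3 neighbourhood of the two conjugate stripe bins."""
    F = np.abs(np.fft.fftshift(np.fft.fft2(pixels))) ** 2
    n = pixels.shape[0]
    a = math.radians(orient_deg)
    fr, fc = int(round(cycles * math.sin(a))), int(round(cycles * math.cos(a)))
    c = n // 2
    total = 0.0
    for sr, sc in ((fr, fc), (-fr, -fc)):
        total += F[c + sr - 1 : c + sr + 2, c + sc - 1 : c + sc + 2].sum()
    return total


class TestFftDenoise:
    def test_stripe_bins_detected_and_power_removed(self, striped_phantom):
        amp, cycles, orient = striped_phantom.spec.periodic_noise
        img = striped_phantom.ute.normalized()
        out, spike_count = df.fft_denoise(img)
        assert spike_count >= 2
        p_before = _stripe_power(img.pixels, cycles, orient)
        p_after = _stripe_power(out.pixels, cycles, orient)
        assert p_after <= 0.1 * p_before

    def test_spike_suppression_preserves_clean_image(self, noiseless_phantom):
        """Without periodic noise only false-positive bins can fire; the
        spike-suppression mechanism must leave the image essentially
        unchanged (relative L2 well under 5%)."""
        img = noiseless_phantom.ute.normalized()
        out, spike_count = df.fft_denoise(img, FrequencyFilterSpec(lowpass_frac=None))
        assert spike_count < 20
        rel = np.linalg.norm(out.pixels - img.pixels) / np.linalg.norm(img.pixels)
        assert rel < 0.05

    def test_constant_image_is_dc_only(self):
        img = _img(np.full((64, 64), 0.4))
        out, spike_count = df.fft_denoise(img, FrequencyFilterSpec(lowpass_frac=None))
        assert spike_count == 0

    def test_spectral_power_never_increases(self, striped_phantom):
        """The filter only zeroes or attenuates bins, so total spectral
        power of the (un-normalised) reconstruction cannot grow."""
        img = striped_phantom.ute.normalized()
        p_in = (np.abs(np.fft.fft2(img.pixels)) ** 2).sum()
        for spec in (FrequencyFilterSpec(), FrequencyFilterSpec(lowpass_frac=None)):
            out, _ = df.fft_denoise(img, spec, normalize=False)
            p_out = (np.abs(np.fft.fft2(out.pixels)) ** 2).sum()
            assert p_out <= p_in * (1 + 1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FrequencyFilterSpec(protect_radius_frac=0.6)
        with pytest.raises(ValueError):
            FrequencyFilterSpec(spike_z=0.0)


class TestEdgeMap:
    def test_constant_image_has_no_edges(self):
        out = df.edge_map(_img(np.full((32, 32), 0.5)))
        assert np.allclose(out.pixels, 0.0)

    def test_step_edge_peaks_at_step(self):
        arr = np.zeros((32, 32))
        arr[:, 16:] = 1.0
        out = df.edge_map(_img(arr))
        assert set(np.argmax(out.pixels, axis=1)) <= {15, 16}

    def test_fascia_ring_produces_ridges_at_truth_boundaries(self, noiseless_phantom):
        """Within a band around the fascia annulus, the strong gradient
        responses trace the inner/outer truth boundaries to within 1 px."""
        import scipy.ndimage as ndi

        out = noiseless_phantom
        edges = df.edge_map(out.ute)
        fascia = out.truth.binary("fascia")
        band = ndi.binary_dilation(fascia, iterations=3)
        strong = band & (edges.pixels > 0.5 * edges.pixels[band].max())
        assert strong.sum() > 100  # responses all around the ring
        boundary = fascia ^ ndi.binary_erosion(fascia)
        near_boundary = ndi.binary_dilation(boundary, iterations=1)
        assert (strong & ~near_boundary).sum() / strong.sum() < 0.05


def _brute_force_wcss_k2(values: np.ndarray) -> float:
    """Independent oracle: optimal 1-D 2-means is a split of the sorted
    values; enumerate every split point exhaustively."""
    v = np.sort(values)
    best = math.inf
    for split in range(1, len(v)):
        a, b = v[:split], v[split:]
        wcss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        best = min(best, wcss)
    return best


class TestKmeans:
    def test_separable_three_level_image_is_exact(self):
        arr = np.repeat([0.1, 0.5, 0.9], 27).reshape(9, 9)
        cr = df.kmeans_intensity(_img(arr), k=3, seed=0)
        assert np.allclose(cr.centroids, [0.1, 0.5, 0.9])
        assert cr.wcss == pytest.approx(0.0, abs=1e-20)

    def test_same_seed_reproduces_labels_and_wcss(self, default_phantom):
        scaled, _ = df.region_specific_scale(default_phantom.pair)
        sub = df.subtract(default_phantom.pair, scaled_ute=scaled)
        a = df.kmeans_intensity(sub, seed=42)
        b = df.kmeans_intensity(sub, seed=42)
        assert a.wcss == b.wcss
        assert np.array_equal(a.labels.labels, b.labels.labels)
        assert a.replicate_seeds == b.replicate_seeds

    def test_matches_exhaustive_partition_oracle_on_tiny_images(self):
        rng = np.random.default_rng(2024)
        for trial in range(20):
            values = rng.uniform(0, 1, 16)
            cr = df.kmeans_intensity(_img(values.reshape(4, 4)), k=2, seed=trial)
            oracle = _brute_force_wcss_k2(values)
            assert cr.wcss == pytest.approx(oracle, rel=1e-9)

    def test_highest_cluster_covers_fascia(self, default_phantom):
        scaled, _ = df.region_specific_scale(
            default_phantom.pair, roi=default_phantom.truth.binary("muscle")
        )
        sub = df.subtract(default_phantom.pair, scaled_ute=scaled)
        cr = df.kmeans_intensity(sub, k=3, seed=0)
        fascia = default_phantom.truth.binary("fascia")
        top = cr.labels.labels == 3
        recall = (top & fascia).sum() / fascia.sum()
        assert recall >= 0.80

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            df.kmeans_intensity(_img(np.zeros((4, 4))), k=3, seed=0)


class TestWatershed:
    @staticmethod
    def _disk(center, radius, size=80):
        yy, xx = np.mgrid[0:size, 0:size]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    def test_disjoint_blobs_yield_one_region_each(self):
        arr = (self._disk((20, 20), 8) | self._disk((60, 60), 8)).astype(float)
        ws = df.watershed_segment(_img(arr), threshold=0.6)
        assert ws.n_regions == 2
        import scipy.ndimage as ndi

        cc, n = ndi.label(arr > 0.6)
        for i in range(1, n + 1):
            labs = np.unique(ws.labels.labels[cc == i])
            labs = labs[labs > 0]
            assert len(labs) == 1

    def test_dumbbell_splits_at_the_neck(self):
        a = self._disk((40, 30), 12)
        b = self._disk((40, 50), 12)
        arr = (a | b).astype(float)
        ws = df.watershed_segment(_img(arr), threshold=0.6)
        assert ws.n_regions == 2
        # ridge (label 0 inside foreground) lies at the minimum-width column
        fg = arr > 0.6
        ridge_cols = np.nonzero((ws.labels.labels == 0) & fg)[1]
        assert ridge_cols.size > 0
        assert abs(np.median(ridge_cols) - 40) <= 1.0

    def test_empty_foreground_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            ws = df.watershed_segment(_img(np.zeros((30, 30))), threshold=0.6)
        assert ws.n_regions == 0
        assert not ws.labels.binary().any()

    def test_region_count_equals_component_count_when_separated(self):
        rng = np.random.default_rng(9)
        arr = np.zeros((120, 120))
        centers = [(20, 20), (20, 90), (80, 30), (95, 95), (60, 60)]
        for c in centers:
            arr[self._disk(c, 9, size=120)] = 1.0
        ws = df.watershed_segment(_img(arr), threshold=0.6)
        assert ws.n_regions == len(centers)


class TestFasciaMask:
    def test_phantom_dice_above_080(self, default_phantom):
        scaled, _ = df.region_specific_scale(
            default_phantom.pair, roi=default_phantom.truth.binary("muscle")
        )
        sub = df.subtract(default_phantom.pair, scaled_ute=scaled)
        cr = df.kmeans_intensity(sub, k=3, seed=0)
        mask = df.fascia_mask_from_clusters(cr, sub)
        m = df.dice_jaccard(mask, default_phantom.truth.binary("fascia"))
        assert m.dice >= 0.80

    def test_all_zero_subtraction_gives_empty_mask(self, caplog):
        import logging

        arr = np.zeros((64, 64))
        arr[0, 0] = 1e-9  # distinct values for clustering
        arr[0, 1] = 2e-9
        img = _img(np.zeros((64, 64)))
        cr = df.kmeans_intensity(_img(arr), k=3, seed=0)
        with caplog.at_level(logging.WARNING):
            mask = df.fascia_mask_from_clusters(cr, img)
        assert not mask.binary().any()

    def test_broken_ring_is_not_hallucinated_closed(self, default_phantom):
        scaled, _ = df.region_specific_scale(
            default_phantom.pair, roi=default_phantom.truth.binary("muscle")
        )
        sub = df.subtract(default_phantom.pair, scaled_ute=scaled)
        # zero out one angular sector of the subtraction image
        n = sub.shape[0]
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        theta = np.arctan2(yy - c, xx - c)
        sector = (theta > 0.0) & (theta < np.pi / 4)
        pix = sub.pixels.copy()
        pix[sector] = 0.0
        broken = sub.with_pixels(pix)
        cr = df.kmeans_intensity(broken, k=3, seed=0)
        mask = df.fascia_mask_from_clusters(cr, broken)
        assert not (mask.binary() & sector).any()
        assert mask.binary().any()  # remaining arc still segmented


class TestPipelineOrderProperty:
    def test_fft_before_kmeans_does_not_hurt_dice(self, striped_phantom):
        """On a periodically corrupted phantom, FFT spike suppression before
        K-means must produce at least the Dice of K-means alone."""
        out = striped_phantom
        scaled, _ = df.region_specific_scale(out.pair, roi=out.truth.binary("muscle"))
        sub = df.subtract(out.pair, scaled_ute=scaled)
        truth = out.truth.binary("fascia")

        cr_plain = df.kmeans_intensity(sub, k=3, seed=0)
        dice_plain = df.dice_jaccard(
            df.fascia_mask_from_clusters(cr_plain, sub), truth
        ).dice

        den, _ = df.fft_denoise(sub)
        cr_fft = df.kmeans_intensity(den, k=3, seed=0)
        dice_fft = df.dice_jaccard(
            df.fascia_mask_from_clusters(cr_fft, den), truth
        ).dice
        assert dice_fft >= dice_plain
        assert dice_fft >= 0.80
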