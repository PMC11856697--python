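"""Segmentation phase: FFT-domain denoising, K-means clustering, watershed.

Periodic interference (gradient or RF pickup) concentrates into bright
spikes in the centred log-magnitude spectrum; those bins are suppressed,
the essential low-frequency content near DC is protected, and an optional
Gaussian low-pass removes residual high-frequency components. Intensity
K-means (k = 3, ten replicates, best within-cluster sum of squares)
separates fascia / muscle-fat / background classes on the subtraction
image, and a marker-free watershed of the negated distance transform
splits touching bright regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.segmentation import watershed as _skimage_watershed

from .core import LabelMask, SliceImage, normalize01

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyFilterSpec",
    "ClusterResult",
    "WatershedResult",
    "fft_denoise",
    "edge_map",
    "kmeans_intensity",
    "watershed_segment",
    "fascia_mask_from_clusters",
]


@dataclass(frozen=True)
class FrequencyFilterSpec:
    """Settings for FFT spike suppression.

    ``protect_radius_frac`` is the radius (fraction of the smaller grid
    dimension) of the central disk around DC that is never modified;
    ``spike_z`` the z-score threshold on the log-magnitude outside it;
    ``lowpass_frac`` the Gaussian low-pass cutoff D0 as a fraction of the
    Nyquist radius (``None`` disables the low-pass).
    """

    protect_radius_frac: float = 0.08
    spike_z: float = 3.5
    lowpass_frac: float | None = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.protect_radius_frac < 0.5:
            raise ValueError("protect_radius_frac must be in (0, 0.5)")
        if self.spike_z <= 0:
            raise ValueError("spike_z must be > 0")
        if self.lowpass_frac is not None and self.lowpass_frac <= 0:
            raise ValueError("lowpass_frac must be > 0 or None")


@dataclass
class ClusterResult:
    """K-means clustering of pixel intensities.

    Labels run 1..k ordered by ascending centroid; ``wcss`` is the best
    (minimum) within-cluster sum of squares over the replicates.
    """

    labels: LabelMask
    centroids: np.ndarray
    wcss: float
    replicate_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if np.any(np.diff(self.centroids) < 0):
            raise ValueError("centroids must be sorted ascending")


@dataclass
class WatershedResult:
    labels: LabelMask
    n_regions: int
    threshold_used: float


def _centered_radius_grid(shape: tuple[int, int]) -> np.ndarray:
    rows = np.arange(shape[0]) - shape[0] // 2
    cols = np.arange(shape[1]) - shape[1] // 2
    return np.hypot(rows[:, None], cols[None, :])


def fft_denoise(
    img: SliceImage,
    spec: FrequencyFilterSpec | None = None,
    normalize: bool = True,
) -> tuple[SliceImage, int]:
    """Suppress periodic-noise spikes in the frequency domain.

    The centred log-magnitude spectrum ``log(1+|F|)`` is thresholded at
    mean + spike_z·std outside the protected central disk; flagged bins and
    their conjugate mirrors are zeroed, the optional Gaussian low-pass is
    applied, and the inverse transform (real part) is min-max normalised to
    [0, 1]. Returns the filtered slice and the number of suppressed bins.
    """
    if spec is None:
        spec = FrequencyFilterSpec()
    p = img.pixels.astype(float)
    F = np.fft.fftshift(np.fft.fft2(p))
    logmag = np.log1p(np.abs(F))
    r = _centered_radius_grid(p.shape)
    protected = r <= spec.protect_radius_frac * min(p.shape)
    outside = ~protected
    mu = float(logmag[outside].mean())
    sd = float(logmag[outside].std())
    if sd == 0:
        spikes = np.zeros_like(protected)
    else:
        spikes = outside & (logmag > mu + spec.spike_z * sd)
    # conjugate symmetry: mirror each spike bin through the DC bin
    cr, cc = p.shape[0] // 2, p.shape[1] // 2
    sr, sc = np.nonzero(spikes)
    mr = (2 * cr - sr) % p.shape[0]
    mc = (2 * cc - sc) % p.shape[1]
    full = spikes.copy()
    full[mr, mc] = True
    full &= ~protected
    spike_count = int(spikes.sum())
    F = np.where(full, 0.0, F)
    if spec.lowpass_frac is not None:
        d0 = spec.lowpass_frac * (min(p.shape) / 2.0)
        F = F * np.exp(-(r ** 2) / (2.0 * d0 ** 2))
    out = np.real(np.fft.ifft2(np.fft.ifftshift(F)))
    if normalize:
        out = normalize01(out)
    return img.with_pixels(out), spike_count


def edge_map(img: SliceImage) -> SliceImage:
    """Gradient-magnitude edge map (central finite differences), in [0, 1]."""
    gr, gc = np.gradient(img.pixels.astype(float))
    return img.with_pixels(normalize01(np.hypot(gr, gc)))


def _lloyd_1d(
    values: np.ndarray, init: np.ndarray, max_iter: int = 300, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Lloyd iterations on 1-D data; returns sorted centroids and WCSS."""
    centroids = np.sort(init.astype(float))
    k = centroids.size
    for _ in range(max_iter):
        edges = (centroids[:-1] + centroids[1:]) / 2.0
        assign = np.searchsorted(edges, values)
        sums = np.bincount(assign, weights=values, minlength=k)
        counts = np.bincount(assign, minlength=k)
        new = centroids.copy()
        nonempty = counts > 0
        new[nonempty] = sums[nonempty] / counts[nonempty]
        new = np.sort(new)
        shift = float(np.max(np.abs(new - centroids)))
        centroids = new
        if shift < tol:
            break
    edges = (centroids[:-1] + centroids[1:]) / 2.0
    assign = np.searchsorted(edges, values)
    wcss = float(np.sum((values - centroids[assign]) ** 2))
    return centroids, wcss


def kmeans_intensity(
    img: SliceImage, k: int = 3, replicates: int = 10, seed: int = 0
) -> ClusterResult:
    """K-means clustering of the flattened pixel intensities.

    Each replicate initialises its k centroids by sampling k distinct
    observed intensities uniformly from a seeded RNG, then runs Lloyd
    iterations (Euclidean distance, convergence when the largest centroid
    shift drops below 1e-6, at most 300 iterations). The replicate with
    the lowest within-cluster sum of squares wins; labels are reported
    1..k by ascending centroid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = img.pixels.astype(float).ravel()
    distinct = np.unique(values)
    if distinct.size < k:
        raise ValueError(
            f"image has {distinct.size} distinct values, fewer than k={k}"
        )
    master = np.random.default_rng(seed)
    replicate_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=replicates)]
    best: tuple[float, np.ndarray] | None = None
    for rseed in replicate_seeds:
        rng = np.random.default_rng(rseed)
        init = rng.choice(distinct, size=k, replace=False)
        centroids, wcss = _lloyd_1d(values, init)
        if best is None or wcss < best[0]:
            best = (wcss, centroids)
    assert best is not None
    wcss, centroids = best
    edges = (centroids[:-1] + centroids[1:]) / 2.0
    assign = np.searchsorted(edges, values) + 1  # labels 1..k, ascending centroid
    labels = LabelMask(
        assign.reshape(img.shape).astype(np.int32),
        scheme={i: f"cluster_{i}" for i in range(1, k + 1)},
    )
    return ClusterResult(
        labels=labels, centroids=centroids, wcss=wcss, replicate_seeds=replicate_seeds
    )


def watershed_segment(img: SliceImage, threshold: float = 0.6) -> WatershedResult:
    """Distance-transform watershed of the thresholded foreground.

    The image (assumed normalised to [0, 1]) is binarised at ``threshold``;
    the Euclidean distance of each foreground pixel to the nearest
    background pixel is negated to form basins, non-foreground is excluded
    from flooding, and the 8-connected watershed assigns catchment labels
    with ridge pixels and background set to 0.
    """
    bw = img.pixels > threshold
    if not bw.any():
        logger.warning("watershed_segment: empty foreground at threshold %g", threshold)
        empty = LabelMask(np.zeros(img.shape, dtype=np.int32), scheme={})
        return WatershedResult(labels=empty, n_regions=0, threshold_used=threshold)
    dist = ndi.distance_transform_edt(bw)
    labels = _skimage_watershed(
        -dist, mask=bw, connectivity=2, watershed_line=True
    )
    labels[~bw] = 0
    ids = np.unique(labels)
    ids = ids[ids > 0]
    # relabel to contiguous positive ints
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    labels = remap[labels]
    lm = LabelMask(
        labels, scheme={int(i): f"region_{int(i)}" for i in range(1, ids.size + 1)}
    )
    return WatershedResult(labels=lm, n_regions=int(ids.size), threshold_used=threshold)


def fascia_mask_from_clusters(
    cr: ClusterResult,
    subtraction_img: SliceImage,
    band_px: int = 3,
    min_component_px: int = 5,
) -> LabelMask:
    """Binary fascia mask from the intensity clustering of a subtraction image.

    Fascia is the cluster with the highest centroid (the subtraction image
    is constructed so connective tissue is brightest). Its connected
    components are kept only where they touch a band around the boundary
    of the largest mid-intensity component (the muscle/fat interface where
    deep fascia lives), which rejects isolated bright specks such as bone
    or noise.
    """
    k = int(cr.centroids.size)
    fascia_cand = cr.labels.labels == k
    if not fascia_cand.any() or float(subtraction_img.pixels.max()) == 0.0:
        logger.warning("fascia_mask_from_clusters: no bright cluster content")
        return LabelMask(np.zeros(cr.labels.shape, dtype=np.int32), scheme={1: "fascia"})

    # anchor band: boundary of the largest component among mid clusters
    mid = (cr.labels.labels > 1) & (cr.labels.labels < k) if k > 2 else (
        cr.labels.labels == 1
    )
    band = None
    if mid.any():
        lab, n = ndi.label(mid)
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        anchor = lab == (int(np.argmax(sizes)) + 1)
        dil = ndi.binary_dilation(anchor, iterations=band_px)
        ero = ndi.binary_erosion(anchor, iterations=band_px)
        band = dil & ~ero
    comp, n = ndi.label(fascia_cand, structure=np.ones((3, 3), dtype=bool))
    keep = np.zeros_like(fascia_cand)
    for i in range(1, n + 1):
        comp_i = comp == i
        if comp_i.sum() < min_component_px:
            continue
        if band is None or (comp_i & band).any():
            keep |= comp_i
    if not keep.any():
        logger.warning("fascia_mask_from_clusters: no candidate component kept")
    return LabelMask(keep.astype(np.int32), scheme={1: "fascia"})
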