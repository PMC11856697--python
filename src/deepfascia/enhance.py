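"""Image enhancement and dual-echo subtraction.

The enhancement phase prepares each slice for segmentation: a
statistics-driven contrast stretch, a white top-hat that emphasises thin
bright features, and a locally adaptive Wiener filter for noise. The
dual-echo stage scales the ultra-short-TE image so a non-target region
(muscle by default) matches the short-TE image, then subtracts the echoes
to isolate short-T2* connective tissue as a bright structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk, white_tophat

from .core import DualEchoPair, LabelMask, SliceImage, as_bool_mask, normalize01

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingResult",
    "SnrMeasurement",
    "contrast_adjust",
    "top_hat",
    "wiener_denoise",
    "estimate_muscle_roi",
    "region_specific_scale",
    "subtract",
    "measure_snr",
]


@dataclass
class ScalingResult:
    """Outcome of region-specific intensity matching between echoes."""

    factor: float
    roi: LabelMask
    method: str  # "median-ratio" or "blended"
    pre_match_stats: dict[str, tuple[float, float]]  # echo -> (mean, median)
    post_match_stats: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"scale factor must be > 0, got {self.factor}")


@dataclass
class SnrMeasurement:
    signal_roi_mean: float
    background_roi_std: float

    @property
    def snr(self) -> float:
        return self.signal_roi_mean / self.background_roi_std


def contrast_adjust(img: SliceImage) -> SliceImage:
    """Linear contrast stretch windowed at mean ± 2·std.

    The input window is ``[mean - 2*std, mean + 2*std]`` intersected with
    the observed intensity range, mapped linearly onto [0, 1]; values
    outside the window saturate. A constant image cannot be windowed and is
    rescaled by its maximum (zeros stay zeros) with a warning.
    """
    p = img.pixels.astype(float)
    mu = float(p.mean())
    sd = float(p.std())
    if sd == 0:
        logger.warning("contrast_adjust: constant image, rescaling by max")
        mx = float(p.max())
        return img.with_pixels(p / mx if mx > 0 else np.zeros_like(p))
    lo = max(mu - 2.0 * sd, float(p.min()))
    hi = min(mu + 2.0 * sd, float(p.max()))
    out = np.clip((p - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(out)


def top_hat(img: SliceImage, radius_px: int = 10) -> SliceImage:
    """White top-hat (image minus its opening) with a disk element.

    Suppresses structures wider than the disk while retaining thin bright
    features such as a fascia ring; the result is non-negative.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    if 2 * radius_px + 1 > min(img.shape):
        raise ValueError(
            f"structuring element (radius {radius_px}) exceeds image {img.shape}"
        )
    out = white_tophat(img.pixels.astype(float), footprint=disk(radius_px))
    return img.with_pixels(np.maximum(out, 0.0))


def wiener_denoise(img: SliceImage, window: tuple[int, int] = (20, 20)) -> SliceImage:
    """Locally adaptive Wiener filter.

    Per-pixel local mean μ and variance σ² are estimated over ``window``;
    the output is ``μ + max(σ² - ν, 0)/max(σ², ν) · (x - μ)`` with noise
    power ν taken as the mean of the local variances. Homogeneous regions
    are smoothed toward their mean; structure with variance above the noise
    floor passes through.
    """
    wr, wc = int(window[0]), int(window[1])
    if wr < 1 or wc < 1:
        raise ValueError(f"window dims must be >= 1, got {window}")
    if wr > img.shape[0] or wc > img.shape[1]:
        raise ValueError(f"window {window} exceeds image dims {img.shape}")
    p = img.pixels.astype(float)
    # reflective boundaries keep local stats unbiased at the image edge
    mu = ndi.uniform_filter(p, size=(wr, wc), mode="reflect")
    mu2 = ndi.uniform_filter(p * p, size=(wr, wc), mode="reflect")
    var = np.maximum(mu2 - mu * mu, 0.0)
    noise = float(var.mean())
    denom = np.maximum(var, noise)
    gain = np.divide(
        np.maximum(var - noise, 0.0),
        denom,
        out=np.zeros_like(var),
        where=denom > 0,
    )
    return img.with_pixels(mu + gain * (p - mu))


def estimate_muscle_roi(shte: SliceImage, erode_px: int = 3) -> LabelMask:
    """Automatic non-target (muscle) ROI from the short-TE image.

    Muscle is the dominant tissue: the largest connected component of
    pixels within ±20% of the foreground median intensity, eroded a few
    pixels to stay clear of boundaries.
    """
    p = normalize01(shte.pixels)
    fg = p > 0.1
    if not fg.any():
        raise ValueError("short-TE image has no foreground to estimate an ROI from")
    med = float(np.median(p[fg]))
    mid = fg & (np.abs(p - med) <= 0.2 * med)
    lab, n = ndi.label(mid)
    if n == 0:
        raise ValueError("no mid-intensity component found for the muscle ROI")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    roi = lab == (int(np.argmax(sizes)) + 1)
    if erode_px > 0:
        eroded = ndi.binary_erosion(roi, iterations=erode_px)
        if eroded.any():
            roi = eroded
    return LabelMask(roi.astype(np.int32), scheme={1: "muscle_roi"})


def region_specific_scale(
    pair: DualEchoPair,
    roi: LabelMask | np.ndarray | None = None,
    blend_tolerance: float = 0.2,
) -> tuple[SliceImage, ScalingResult]:
    """Scale the UTE image so a non-target region matches the short-TE image.

    The factor is the median ratio ``median(shTE|roi) / median(UTE|roi)``;
    mean and median ratios are compared and, when they disagree by more
    than ``blend_tolerance`` (relative), their average is used instead
    (method "blended"). Scaling the lower-SNR ultra-short echo up into the
    short-TE intensity regime makes the subsequent subtraction cancel the
    non-target tissue.
    """
    if roi is None:
        roi = estimate_muscle_roi(pair.shte)
    roi_mask = as_bool_mask(roi)
    if roi_mask.shape != pair.ute.shape:
        raise ValueError("ROI shape does not match the echo grids")
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    ute_vals = pair.ute.pixels[roi_mask].astype(float)
    shte_vals = pair.shte.pixels[roi_mask].astype(float)
    med_u, med_s = float(np.median(ute_vals)), float(np.median(shte_vals))
    mean_u, mean_s = float(ute_vals.mean()), float(shte_vals.mean())
    if med_u <= 0:
        raise ValueError("degenerate ROI: UTE median is not positive")
    median_ratio = med_s / med_u
    mean_ratio = mean_s / mean_u if mean_u > 0 else median_ratio
    discrepancy = abs(mean_ratio - median_ratio) / median_ratio
    if discrepancy > blend_tolerance:
        factor = 0.5 * (mean_ratio + median_ratio)
        method = "blended"
        logger.info(
            "mean/median scale ratios disagree by %.1f%%; blending (%.4f, %.4f)",
            100 * discrepancy, mean_ratio, median_ratio,
        )
    else:
        factor = median_ratio
        method = "median-ratio"
    scaled = pair.ute.with_pixels(pair.ute.pixels.astype(float) * factor)
    roi_lm = roi if isinstance(roi, LabelMask) else LabelMask(
        roi_mask.astype(np.int32), scheme={1: "roi"}
    )
    result = ScalingResult(
        factor=factor,
        roi=roi_lm,
        method=method,
        pre_match_stats={
            "ute": (mean_u, med_u),
            "shte": (mean_s, med_s),
        },
        post_match_stats={
            "scaled_ute": (mean_u * factor, med_u * factor),
            "shte": (mean_s, med_s),
        },
    )
    if method == "median-ratio":
        post_ratio = (med_u * factor) / med_s
        assert abs(post_ratio - 1.0) < 1e-6, "median-ratio scaling invariant violated"
    return scaled, result


def subtract(pair: DualEchoPair, scaled_ute: SliceImage | None = None) -> SliceImage:
    """Echo difference (scaled UTE − shTE), clipped at zero and normalised.

    Negative residuals — where the second echo locally exceeds the (scaled)
    first — carry no connective-tissue signal and are clipped; their count
    is logged. The result is min-max normalised to [0, 1] so downstream
    absolute thresholds apply.
    """
    first = scaled_ute if scaled_ute is not None else pair.ute
    if first.shape != pair.shte.shape:
        raise ValueError(f"shape mismatch: {first.shape} vs {pair.shte.shape}")
    diff = first.pixels.astype(float) - pair.shte.pixels.astype(float)
    n_neg = int((diff < 0).sum())
    if n_neg:
        logger.info("subtract: clipped %d negative residual pixels", n_neg)
    return first.with_pixels(normalize01(np.clip(diff, 0.0, None)))


def measure_snr(
    img: SliceImage,
    signal_roi: LabelMask | np.ndarray,
    background_roi: LabelMask | np.ndarray,
) -> SnrMeasurement:
    """SNR as mean over a signal ROI divided by std over a background ROI."""
    sig = as_bool_mask(signal_roi)
    bg = as_bool_mask(background_roi)
    if not sig.any() or not bg.any():
        raise ValueError("both ROIs must be nonempty")
    if (sig & bg).any():
        raise ValueError("signal and background ROIs must be disjoint")
    bg_std = float(img.pixels[bg].std())
    if bg_std == 0:
        raise ValueError("degenerate background ROI: zero standard deviation")
    return SnrMeasurement(
        signal_roi_mean=float(img.pixels[sig].mean()),
        background_roi_std=bg_std,
    )
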