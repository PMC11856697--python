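"""Core in-memory containers shared by every pipeline stage.

All processing is 2-D and slice-wise: the atom is a single axial grayscale
slice with its in-plane pixel spacing. Physical positions are
``index * spacing`` in millimetres, with 0-based ``[row, col]`` indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SliceImage",
    "DualEchoPair",
    "LabelMask",
    "normalize01",
]


def normalize01(pixels: np.ndarray) -> np.ndarray:
    """Min-max rescale an array to [0, 1]; a constant array maps to zeros."""
    pixels = np.asarray(pixels, dtype=float)
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi <= lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


@dataclass
class SliceImage:
    """One 2-D grayscale slice with its geometry.

    Parameters
    ----------
    pixels : ndarray
        2-D float array indexed ``[row, col]``.
    spacing : (float, float)
        In-plane pixel spacing ``(row_mm, col_mm)``, both > 0.
    slice_thickness : float
        Through-plane extent in mm (> 0).
    intensity_range_hint : (float, float), optional
        Nominal display window; not used by processing.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0
    intensity_range_hint: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.floating):
            self.pixels = self.pixels.astype(np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain NaN or Inf")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "SliceImage":
        """A copy of this slice carrying new pixel values, same geometry."""
        return replace(self, pixels=np.asarray(pixels), intensity_range_hint=None)

    def normalized(self) -> "SliceImage":
        return self.with_pixels(normalize01(self.pixels))


@dataclass
class DualEchoPair:
    """Co-registered ultra-short-TE and short-TE images of one slice.

    ``ute`` is acquired at ``te1`` (typically ~0.05 ms) while short-T2*
    tissue such as fascia still has signal; ``shte`` at ``te2`` after that
    signal has decayed. Their scaled difference isolates connective tissue.
    """

    ute: SliceImage
    shte: SliceImage
    te1: float
    te2: float

    def __post_init__(self) -> None:
        if not self.te1 < self.te2:
            raise ValueError(f"te1 must be < te2, got {self.te1} >= {self.te2}")
        if self.ute.shape != self.shte.shape:
            raise ValueError(
                f"echo grids differ: {self.ute.shape} vs {self.shte.shape}"
            )
        if self.ute.spacing != self.shte.spacing:
            raise ValueError(
                f"echo spacings differ: {self.ute.spacing} vs {self.shte.spacing}"
            )


@dataclass
class LabelMask:
    """Integer per-pixel tissue labels on a slice grid.

    Label 0 is reserved for background; every nonzero label present in
    ``labels`` must appear in ``scheme``.
    """

    labels: np.ndarray
    scheme: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        self.scheme = dict(self.scheme)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.scheme)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from scheme")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def binary(self, label: int | str | None = None) -> np.ndarray:
        """Boolean mask of one tissue (by id or name), or of all foreground."""
        if label is None:
            return self.labels != 0
        if isinstance(label, str):
            matches = [k for k, v in self.scheme.items() if v == label]
            if not matches:
                raise KeyError(f"tissue {label!r} not in scheme {self.scheme}")
            label = matches[0]
        return self.labels == label


def as_bool_mask(mask: "LabelMask | np.ndarray") -> np.ndarray:
    """Coerce a LabelMask or array to a boolean foreground mask."""
    if isinstance(mask, LabelMask):
        return mask.binary()
    return np.asarray(mask) != 0
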