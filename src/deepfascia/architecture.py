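"""Muscle-architecture metrics from fascicle streamlines and a muscle mask.

Consumes fiber tracts produced elsewhere (DTI tractography or the built-in
pennate generator) as polylines in physical mm coordinates, applies the
5–200 mm tract-length filter, and reports fascicle length Lf, pennation
angle θp relative to the muscle's line of action, muscle volume V, and
physiological cross-sectional area PCSA = V / mean(Lf).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StreamlineSet",
    "ArchitectureReport",
    "filter_tracts",
    "fascicle_lengths",
    "pennation_angles",
    "line_of_action_estimate",
    "architecture_report",
]


@dataclass
class StreamlineSet:
    """Polyline fiber tracts in physical mm coordinates."""

    tracts: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for i, t in enumerate(self.tracts):
            arr = np.asarray(t, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(
                    f"tract {i} must be an (n>=2, 3) array, got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"tract {i} contains non-finite coordinates")
            cleaned.append(arr)
        self.tracts = cleaned

    @property
    def count(self) -> int:
        return len(self.tracts)

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)


@dataclass
class ArchitectureReport:
    """Summary architecture parameters of one muscle."""

    n_tracts_in: int
    n_tracts_kept: int
    fascicle_length_mean_mm: float
    fascicle_length_sd_mm: float
    pennation_mean_deg: float
    pennation_sd_deg: float
    muscle_volume_mm3: float
    pcsa_mm2: float
    line_of_action: np.ndarray

    def __post_init__(self) -> None:
        expected = self.muscle_volume_mm3 / self.fascicle_length_mean_mm
        if not np.isclose(self.pcsa_mm2, expected, rtol=1e-12, atol=0.0):
            raise ValueError("PCSA must equal muscle volume / mean fascicle length")


def fascicle_lengths(ts: StreamlineSet) -> np.ndarray:
    """Arc length of every tract in mm (sum of consecutive segment lengths)."""
    if ts.count == 0:
        raise ValueError("streamline set is empty")
    return np.array(
        [float(np.linalg.norm(np.diff(t, axis=0), axis=1).sum()) for t in ts]
    )


def filter_tracts(
    ts: StreamlineSet, min_mm: float = 5.0, max_mm: float = 200.0
) -> StreamlineSet:
    """Keep tracts whose arc length lies in the closed interval [min, max] mm."""
    if not min_mm < max_mm:
        raise ValueError(f"min_mm must be < max_mm, got ({min_mm}, {max_mm})")
    if ts.count == 0:
        return StreamlineSet(tracts=[])
    lengths = fascicle_lengths(ts)
    kept = [t for t, L in zip(ts.tracts, lengths) if min_mm <= L <= max_mm]
    return StreamlineSet(tracts=kept)


def pennation_angles(
    ts: StreamlineSet, line_of_action: Sequence[float]
) -> np.ndarray:
    """Angle (degrees, folded to [0, 90]) between each tract's end-to-end
    chord and the muscle's line of action.

    Fiber orientation is direction-agnostic, so the absolute dot product is
    used. Zero-length chords are skipped with a warning.
    """
    loa = np.asarray(line_of_action, dtype=float)
    n = np.linalg.norm(loa)
    if n == 0:
        raise ValueError("line_of_action must be nonzero")
    loa = loa / n
    if ts.count == 0:
        raise ValueError("streamline set is empty")
    angles = []
    skipped = 0
    for t in ts:
        chord = t[-1] - t[0]
        c = np.linalg.norm(chord)
        if c == 0:
            skipped += 1
            continue
        cosang = np.clip(abs(float(np.dot(chord, loa))) / c, 0.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    if skipped:
        logger.warning("skipped %d zero-length chords in pennation_angles", skipped)
    return np.asarray(angles)


def line_of_action_estimate(
    mask_stack: np.ndarray,
    spacing: tuple[float, float],
    slice_thickness: float,
) -> np.ndarray:
    """Principal axis of the muscle's foreground voxels.

    Coordinates are physical ``(row*spacing, col*spacing, slice*thickness)``
    mm; the estimate is the leading eigenvector of their covariance,
    sign-fixed to a positive through-plane component. A single-slice mask
    has a rank-deficient through-plane covariance and raises.
    """
    stack = np.asarray(mask_stack)
    if stack.ndim != 3:
        raise ValueError(f"mask_stack must be 3-D (slice, row, col), got {stack.shape}")
    if stack.shape[0] < 2:
        raise ValueError(
            "mask stack has a single slice: through-plane covariance is "
            "rank-deficient; supply a line-of-action vector explicitly"
        )
    k, r, c = np.nonzero(stack)
    if k.size == 0:
        raise ValueError("mask stack is empty")
    coords = np.stack(
        [r * spacing[0], c * spacing[1], k * slice_thickness], axis=1
    ).astype(float)
    cov = np.cov(coords.T)
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < 1:
        raise ValueError(
            "degenerate voxel covariance; supply a line-of-action vector explicitly"
        )
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    if axis[2] < 0:
        axis = -axis
    return axis


def architecture_report(
    ts: StreamlineSet,
    mask_stack: np.ndarray,
    spacing: tuple[float, float],
    slice_thickness: float,
    line_of_action: Sequence[float] | None = None,
    min_mm: float = 5.0,
    max_mm: float = 200.0,
) -> ArchitectureReport:
    """Full architecture summary: filter tracts, measure Lf and θp, compute
    muscle volume from the mask stack, and derive PCSA = V / mean(Lf)."""
    from .measure import muscle_size

    kept = filter_tracts(ts, min_mm=min_mm, max_mm=max_mm)
    if kept.count == 0:
        raise ValueError(
            f"no tracts remain after the [{min_mm}, {max_mm}] mm length filter"
        )
    if line_of_action is None:
        loa = line_of_action_estimate(mask_stack, spacing, slice_thickness)
    else:
        loa = np.asarray(line_of_action, dtype=float)
        loa = loa / np.linalg.norm(loa)

    lengths = fascicle_lengths(kept)
    angles = pennation_angles(kept, loa)
    _, volume = muscle_size(mask_stack, spacing, slice_thickness)
    mean_len = float(lengths.mean())
    return ArchitectureReport(
        n_tracts_in=ts.count,
        n_tracts_kept=kept.count,
        fascicle_length_mean_mm=mean_len,
        fascicle_length_sd_mm=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        pennation_mean_deg=float(angles.mean()),
        pennation_sd_deg=float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        muscle_volume_mm3=float(volume),
        pcsa_mm2=float(volume) / mean_len,
        line_of_action=loa,
    )
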