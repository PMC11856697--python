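"""Synthetic dual-echo lower-leg phantom and pennate fiber-tract generator.

The phantom emulates an axial cross-section of the lower leg as nested
concentric compartments — background, subcutaneous fat, a thin deep-fascia
annulus, muscle (optionally split by an aponeurosis-like septum) and bone.
Each tissue follows mono-exponential T2* decay, ``S(TE) = S0·exp(-TE/T2*)``,
evaluated at the two echo times of a dual-echo UTE acquisition. Fascia and
bone have very short T2*, so they retain signal only at the ultra-short
echo: the scaled echo difference lights up connective tissue.

Corruption models: Rician noise (magnitude of signal plus complex Gaussian),
an optional additive sinusoidal interference pattern, and an optional
smooth multiplicative bias field ``exp(polynomial)`` normalised to mean 1.

Geometry is rendered by classifying each pixel centre radially with no
anti-aliasing, so ground-truth masks and thicknesses are exact in pixel
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .architecture import StreamlineSet
from .core import DualEchoPair, LabelMask, SliceImage

__all__ = [
    "TissueSignalModel",
    "PhantomSpec",
    "PhantomOutput",
    "TISSUE_LABELS",
    "default_tissue_models",
    "make_phantom",
    "make_pennate_tracts",
]

#: Label scheme shared by phantom truth masks and downstream segmentations.
TISSUE_LABELS: dict[int, str] = {1: "fat", 2: "fascia", 3: "muscle", 4: "bone"}
_NAME_TO_LABEL = {v: k for k, v in TISSUE_LABELS.items()}


@dataclass(frozen=True)
class TissueSignalModel:
    """Mono-exponential T2* signal model of one tissue.

    ``s0`` is the proton-density amplitude (arbitrary units) and ``t2star``
    the effective transverse decay constant in ms; the signal at echo time
    ``te`` (ms) is ``s0 * exp(-te / t2star)``.
    """

    s0: float
    t2star: float

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")
        if self.t2star <= 0:
            raise ValueError(f"t2star must be > 0, got {self.t2star}")

    def signal_at(self, te: float) -> float:
        return self.s0 * math.exp(-te / self.t2star)


def default_tissue_models() -> dict[str, TissueSignalModel]:
    """Plausible-contrast tissue parameters.

    Chosen to reproduce the qualitative ordering a dual-echo UTE protocol
    relies on — fascia and cortical bone bright only at ultra-short TE,
    muscle and fat persisting to the second echo. They are not calibrated
    to any particular scanner.
    """
    return {
        "fat": TissueSignalModel(s0=0.9, t2star=15.0),
        "muscle": TissueSignalModel(s0=1.0, t2star=25.0),
        "fascia": TissueSignalModel(s0=0.8, t2star=1.2),
        "bone": TissueSignalModel(s0=0.3, t2star=0.4),
        "background": TissueSignalModel(s0=0.0, t2star=1.0),
    }


@dataclass
class PhantomSpec:
    """Geometry, tissue models and corruption settings of the leg phantom.

    All radii/thicknesses are in mm. ``fascia_thickness`` may be a callable
    of polar angle (radians) for a non-uniform fascia. ``periodic_noise``
    is ``(amplitude, cycles_per_image, orientation_deg)``; ``bias_field``
    is a flat list of 2-D polynomial coefficients ``c_ij`` ordered by total
    degree (1, x, y, x², xy, y², ...) on coordinates normalised to [-1, 1].
    """

    grid_size: int = 256
    pixel_spacing: float = 0.5
    leg_radius: float = 55.0
    fat_thickness: float = 8.0
    fascia_thickness: float | Callable[[np.ndarray], np.ndarray] = 1.5
    septum_width: float = 0.0
    bone_radius: float = 10.0
    tissue_models: Mapping[str, TissueSignalModel] = field(
        default_factory=default_tissue_models
    )
    te1: float = 0.05
    te2: float = 5.19
    noise_sigma: float = 0.02
    periodic_noise: tuple[float, float, float] | None = None
    bias_field: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise ValueError(f"grid_size must be >= 64, got {self.grid_size}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.te1 < self.te2:
            raise ValueError("te1 must be < te2")
        for name in ("fat_thickness", "septum_width", "bone_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(TISSUE_LABELS.values()) | {"background"}
        missing -= set(self.tissue_models)
        if missing:
            raise ValueError(f"tissue_models missing {sorted(missing)}")
        fasc = self.max_fascia_thickness()
        if fasc < 0:
            raise ValueError("fascia_thickness must be >= 0")
        if not self.bone_radius + fasc + self.fat_thickness < self.leg_radius:
            raise ValueError(
                "geometry does not nest: require bone_radius + fascia_thickness"
                f" + fat_thickness < leg_radius ({self.bone_radius} + {fasc}"
                f" + {self.fat_thickness} >= {self.leg_radius})"
            )

    def max_fascia_thickness(self) -> float:
        if callable(self.fascia_thickness):
            angles = np.linspace(-np.pi, np.pi, 721)
            return float(np.max(self.fascia_thickness(angles)))
        return float(self.fascia_thickness)


@dataclass
class PhantomOutput:
    """Rendered dual-echo pair with ground truth."""

    ute: SliceImage
    shte: SliceImage
    truth: LabelMask
    true_thickness_mm: float | np.ndarray
    te1: float
    te2: float
    spec: PhantomSpec

    @property
    def pair(self) -> DualEchoPair:
        return DualEchoPair(ute=self.ute, shte=self.shte, te1=self.te1, te2=self.te2)


def _polar_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.grid_size
    c = (n - 1) / 2.0
    idx = np.arange(n, dtype=float)
    y = (idx[:, None] - c) * spec.pixel_spacing  # row -> y (mm)
    x = (idx[None, :] - c) * spec.pixel_spacing  # col -> x (mm)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    return r, theta


def _render_labels(spec: PhantomSpec) -> np.ndarray:
    r, theta = _polar_grid(spec)
    if callable(spec.fascia_thickness):
        fasc = np.asarray(spec.fascia_thickness(theta), dtype=float)
    else:
        fasc = np.full_like(r, float(spec.fascia_thickness))

    fat_outer = spec.leg_radius
    fascia_outer = fat_outer - spec.fat_thickness
    fascia_inner = fascia_outer - fasc

    labels = np.zeros(r.shape, dtype=np.uint8)
    labels[r <= fat_outer] = _NAME_TO_LABEL["fat"]
    inner = r <= fascia_outer
    # fasc == 0 collapses the annulus (fascia_inner == fascia_outer): all muscle
    labels[inner] = np.where(
        r[inner] > fascia_inner[inner],
        _NAME_TO_LABEL["fascia"],
        _NAME_TO_LABEL["muscle"],
    )
    if spec.septum_width > 0:
        # vertical aponeurosis-like septum through the muscle compartment
        n = spec.grid_size
        c = (n - 1) / 2.0
        x_mm = (np.arange(n, dtype=float)[None, :] - c) * spec.pixel_spacing
        in_septum = (np.abs(x_mm) <= spec.septum_width / 2.0) & (
            labels == _NAME_TO_LABEL["muscle"]
        )
        labels[in_septum] = _NAME_TO_LABEL["fascia"]
    labels[r <= spec.bone_radius] = _NAME_TO_LABEL["bone"]
    return labels


def _bias_field(spec: PhantomSpec) -> np.ndarray | None:
    if spec.bias_field is None:
        return None
    coeffs = list(spec.bias_field)
    n = spec.grid_size
    u = np.linspace(-1.0, 1.0, n)
    X, Y = np.meshgrid(u, u, indexing="xy")
    # monomials by total degree: 1, x, y, x2, xy, y2, x3, ...
    terms = []
    deg = 0
    while len(terms) < len(coeffs):
        for i in range(deg, -1, -1):
            terms.append(X ** i * Y ** (deg - i))
            if len(terms) == len(coeffs):
                break
        deg += 1
    poly = sum(c * t for c, t in zip(coeffs, terms))
    fieldmap = np.exp(poly)
    return fieldmap / fieldmap.mean()


def _periodic_pattern(spec: PhantomSpec, phase_offset: float) -> np.ndarray | None:
    if spec.periodic_noise is None:
        return None
    amp, cycles, orient_deg = spec.periodic_noise
    n = spec.grid_size
    rows = np.arange(n, dtype=float)[:, None]
    cols = np.arange(n, dtype=float)[None, :]
    ang = math.radians(orient_deg)
    # phase advances along the direction `orient_deg` (0 deg = along columns)
    phase = 2.0 * np.pi * cycles * (cols * math.cos(ang) + rows * math.sin(ang)) / n
    return amp * np.sin(phase + phase_offset)


def make_phantom(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Render the dual-echo leg phantom described by ``spec``.

    Per pixel, the noiseless value is the tissue signal at the echo time;
    the bias field (if any) multiplies the noiseless signal, Rician noise
    is applied independently per echo, and the periodic pattern (if any)
    is added to both echoes. Images are float32; with ``noise_sigma=0``
    and no corruptions the output is the exact noiseless rendering.
    """
    if spec is None:
        spec = PhantomSpec()
    labels = _render_labels(spec)
    models = dict(spec.tissue_models)
    rng = np.random.default_rng(spec.seed)

    lut_names = {0: "background", **TISSUE_LABELS}
    echoes = []
    bias = _bias_field(spec)
    for te in (spec.te1, spec.te2):
        signal = np.zeros(labels.shape, dtype=np.float64)
        for lab, name in lut_names.items():
            signal[labels == lab] = models[name].signal_at(te)
        if bias is not None:
            signal = signal * bias
        if spec.noise_sigma > 0:
            re = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
            im = rng.normal(0.0, spec.noise_sigma, signal.shape)
            signal = np.hypot(re, im)
        if spec.periodic_noise is not None:
            # interference phase differs between readouts, so the stripes do
            # not simply cancel in the echo subtraction
            periodic = _periodic_pattern(spec, phase_offset=rng.uniform(0, 2 * np.pi))
            signal = signal + periodic
        echoes.append(signal.astype(np.float32))

    spacing = (spec.pixel_spacing, spec.pixel_spacing)
    ute = SliceImage(echoes[0], spacing=spacing)
    shte = SliceImage(echoes[1], spacing=spacing)
    truth = LabelMask(labels.astype(np.int32), scheme=dict(TISSUE_LABELS))
    if callable(spec.fascia_thickness):
        angles = np.linspace(-np.pi, np.pi, 361)
        true_thickness: float | np.ndarray = np.asarray(
            spec.fascia_thickness(angles), dtype=float
        )
    else:
        true_thickness = float(spec.fascia_thickness)
    return PhantomOutput(
        ute=ute,
        shte=shte,
        truth=truth,
        true_thickness_mm=true_thickness,
        te1=spec.te1,
        te2=spec.te2,
        spec=spec,
    )


def make_pennate_tracts(
    n_tracts: int = 1000,
    pennation_deg: float = 20.0,
    line_of_action: Sequence[float] = (0.0, 0.0, 1.0),
    length_range_mm: tuple[float, float] = (5.0, 200.0),
    seed: int = 0,
    points_per_tract: int = 5,
) -> StreamlineSet:
    """Straight fascicle-like tracts at a fixed pennation angle.

    Every tract's chord makes exactly ``pennation_deg`` with
    ``line_of_action``; the azimuth about that axis and the tract length
    (uniform over ``length_range_mm``) are randomised under ``seed``.
    Start points are scattered in a 100 mm cube so the set resembles a
    pennate fascicle field rather than a single bundle.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    if not (0.0 <= pennation_deg < 90.0):
        raise ValueError(f"pennation_deg must be in [0, 90), got {pennation_deg}")
    lo, hi = length_range_mm
    if not lo <= hi:
        raise ValueError(f"length range min must be <= max, got {length_range_mm}")

    loa = np.asarray(line_of_action, dtype=float)
    norm = np.linalg.norm(loa)
    if norm == 0:
        raise ValueError("line_of_action must be nonzero")
    loa = loa / norm
    # orthonormal frame around the line of action
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, loa)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(loa, helper)
    u /= np.linalg.norm(u)
    v = np.cross(loa, u)

    rng = np.random.default_rng(seed)
    theta = math.radians(pennation_deg)
    azimuth = rng.uniform(0.0, 2.0 * np.pi, size=n_tracts)
    lengths = rng.uniform(lo, hi, size=n_tracts)
    starts = rng.uniform(-50.0, 50.0, size=(n_tracts, 3))

    directions = (
        math.cos(theta) * loa[None, :]
        + math.sin(theta)
        * (np.cos(azimuth)[:, None] * u[None, :] + np.sin(azimuth)[:, None] * v[None, :])
    )
    t = np.linspace(0.0, 1.0, points_per_tract)
    tracts = [
        starts[i] + np.outer(t * lengths[i], directions[i]) for i in range(n_tracts)
    ]
    return StreamlineSet(tracts=tracts)
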