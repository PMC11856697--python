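"""Reading and writing the formats the pipeline touches.

NIfTI volumes go through nibabel (spacing taken from/put into the header
zooms), DICOM series through pydicom (slices ordered by through-plane
position, stored slope/intercept applied), streamline tracts through
nibabel's TCK reader or a plain-text polyline format. Label masks are
uint8 NIfTI with the label scheme in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .architecture import StreamlineSet
from .core import LabelMask, SliceImage
from .phantom import PhantomOutput

__all__ = [
    "load_volume",
    "save_image",
    "save_mask",
    "load_mask",
    "load_tracts",
    "save_tracts_text",
    "save_phantom",
]


def _affine_for(spacing: tuple[float, float], slice_thickness: float) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], slice_thickness, 1.0]).astype(float)


def save_image(
    slices: SliceImage | list[SliceImage],
    path: str | Path,
    dtype=np.float32,
) -> Path:
    """Write one slice or an ordered slice stack as a NIfTI volume."""
    if isinstance(slices, SliceImage):
        slices = [slices]
    first = slices[0]
    for s in slices[1:]:
        if s.shape != first.shape or s.spacing != first.spacing:
            raise ValueError("all slices in a stack must share grid and spacing")
    data = np.stack([s.pixels for s in slices], axis=-1).astype(dtype)
    img = nib.Nifti1Image(data, _affine_for(first.spacing, first.slice_thickness))
    img.header.set_zooms((first.spacing[0], first.spacing[1], first.slice_thickness))
    path = Path(path)
    nib.save(img, str(path))
    return path


def _load_nifti(path: Path) -> list[SliceImage]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    thickness = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 1.0
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D/3-D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN/Inf")
    return [
        SliceImage(pixels=data[:, :, k], spacing=spacing, slice_thickness=thickness)
        for k in range(data.shape[2])
    ]


def _load_dicom_series(path: Path) -> list[SliceImage]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:  # non-DICOM files in the directory are skipped
            continue
        datasets.append((f, ds))
    if not datasets:
        raise IOError(f"no readable DICOM files in {path}")

    spacings = set()
    for f, ds in datasets:
        if "PixelSpacing" not in ds:
            raise ValueError(f"{f}: missing PixelSpacing tag (0028,0030)")
        spacings.add((float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])))
    if len(spacings) > 1:
        raise ValueError(f"{path}: mixed PixelSpacing across the series: {spacings}")
    spacing = spacings.pop()

    def z_position(ds) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=lambda fd: z_position(fd[1]))
    out = []
    for f, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        thickness = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
        out.append(SliceImage(pixels=arr, spacing=spacing, slice_thickness=thickness))
    return out


def load_volume(path: str | Path, format: str | None = None) -> list[SliceImage]:
    """Load an ordered slice stack from a NIfTI file or a DICOM series dir.

    ``format`` is ``"nifti"`` or ``"dicom-series"``; when omitted it is
    inferred (directory → DICOM series, file → NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom-series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def save_mask(mask: LabelMask, path: str | Path, slice_thickness: float = 1.0,
              spacing: tuple[float, float] = (1.0, 1.0)) -> Path:
    """Write a label mask as uint8 NIfTI with the scheme in a JSON sidecar."""
    if int(mask.labels.max(initial=0)) > 255 or int(mask.labels.min(initial=0)) < 0:
        raise ValueError("labels must fit in uint8 for NIfTI export")
    path = Path(path)
    data = mask.labels.astype(np.uint8)[..., None]
    img = nib.Nifti1Image(data, _affine_for(spacing, slice_thickness))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii or .nii.gz
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(
        json.dumps({"scheme": {str(k): v for k, v in mask.scheme.items()}}, indent=2)
    )
    return path


def load_mask(path: str | Path) -> LabelMask:
    """Reload a label mask written by :func:`save_mask`."""
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if labels.ndim == 3:
        if labels.shape[2] != 1:
            raise ValueError(f"{path}: expected a single-slice mask")
        labels = labels[:, :, 0]
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    scheme: dict[int, str] = {}
    if sidecar.exists():
        raw = json.loads(sidecar.read_text()).get("scheme", {})
        scheme = {int(k): v for k, v in raw.items()}
    else:
        scheme = {int(v): f"label_{int(v)}" for v in np.unique(labels) if v != 0}
    return LabelMask(labels.astype(np.int32), scheme=scheme)


def load_tracts(path: str | Path) -> StreamlineSet:
    """Load streamlines from a TCK file or the plain-text polyline format."""
    path = Path(path)
    if path.suffix.lower() == ".tck":
        tck = nib.streamlines.load(str(path))
        return StreamlineSet(tracts=[np.asarray(s, dtype=float) for s in tck.streamlines])
    return _load_tracts_text(path)


def _load_tracts_text(path: Path) -> StreamlineSet:
    """Plain-text tracts: one point per line as ``x y z`` (mm); blank lines
    or lines starting with '#' separate tracts."""
    tracts: list[np.ndarray] = []
    current: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            if len(current) >= 2:
                tracts.append(np.asarray(current))
            current = []
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 'x y z' per line, got {line!r}")
        current.append([float(v) for v in parts])
    if len(current) >= 2:
        tracts.append(np.asarray(current))
    if not tracts:
        raise ValueError(f"{path}: no tracts found")
    return StreamlineSet(tracts=tracts)


def save_tracts_text(ts: StreamlineSet, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for i, t in enumerate(ts):
        lines.append(f"# tract {i}")
        lines.extend(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in t)
    path.write_text("\n".join(lines) + "\n")
    return path


def save_phantom(out: PhantomOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write a rendered phantom: one NIfTI per echo, the truth mask, and a
    JSON sidecar recording the generating parameters and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ute": save_image(out.ute, out_dir / "ute.nii.gz"),
        "shte": save_image(out.shte, out_dir / "shte.nii.gz"),
        "truth": save_mask(
            out.truth,
            out_dir / "truth.nii.gz",
            spacing=out.ute.spacing,
            slice_thickness=out.ute.slice_thickness,
        ),
    }
    spec = out.spec
    thickness = out.true_thickness_mm
    sidecar = {
        "te1_ms": out.te1,
        "te2_ms": out.te2,
        "seed": spec.seed,
        "grid_size": spec.grid_size,
        "pixel_spacing_mm": spec.pixel_spacing,
        "leg_radius_mm": spec.leg_radius,
        "fat_thickness_mm": spec.fat_thickness,
        "fascia_thickness_mm": (
            list(np.asarray(thickness, dtype=float))
            if isinstance(thickness, np.ndarray)
            else float(thickness)
        ),
        "septum_width_mm": spec.septum_width,
        "bone_radius_mm": spec.bone_radius,
        "noise_sigma": spec.noise_sigma,
        "periodic_noise": spec.periodic_noise,
        "bias_field": list(spec.bias_field) if spec.bias_field else None,
        "tissues": {
            name: {"s0": m.s0, "t2star_ms": m.t2star}
            for name, m in spec.tissue_models.items()
        },
    }
    sidecar_path = out_dir / "phantom.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sidecar_path
    return paths
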