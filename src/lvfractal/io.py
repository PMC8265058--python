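"""Reading and writing cine stacks, masks and results.

Short-axis stacks travel as NIfTI-1 volumes (with a JSON sidecar for
metadata NIfTI cannot carry, e.g. the inter-slice gap and subject id) or
as DICOM series directories with one frame per file.  All physical
quantities in the data model are in millimetres; pixel indices never mix
with mm outside explicit conversions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

RESULTS_SCHEMA_VERSION = "1"

__all__ = [
    "CineStack",
    "StackLoadError",
    "load_stack",
    "save_stack",
    "load_mask_stack",
    "write_results",
    "read_results",
    "write_cohort_csv",
]


class StackLoadError(ValueError):
    """Descriptive failure while assembling a cine stack from disk."""


@dataclass(frozen=True)
class CineStack:
    """Ordered base->apex end-diastolic short-axis slices with mm metadata.

    ``slices`` is an (n_slices, rows, cols) float array.  ``frame_label``
    records how the end-diastolic frame was chosen (provenance, not used
    computationally).
    """

    slices: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0
    frame_label: str = "end-diastole (frame 0)"
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices, dtype=float)
        if arr.ndim != 3:
            raise StackLoadError(f"slices must be 3-D, got shape {arr.shape}")
        if arr.shape[0] < 4:
            raise StackLoadError(
                f"a stack needs >= 4 slices base->apex, got {arr.shape[0]}"
            )
        sp = self.pixel_spacing_mm
        if len(sp) != 2 or sp[0] <= 0 or sp[1] <= 0:
            raise StackLoadError(f"invalid pixel spacing {sp}")
        if self.slice_thickness_mm <= 0:
            raise StackLoadError("slice thickness must be positive")
        if self.slice_gap_mm < 0:
            raise StackLoadError("slice gap cannot be negative")
        object.__setattr__(self, "slices", arr)

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def slice_interval_mm(self) -> float:
        """Centre-to-centre slice spacing: thickness + gap."""
        return self.slice_thickness_mm + self.slice_gap_mm

    def __eq__(self, other) -> bool:  # value semantics incl. the array
        if not isinstance(other, CineStack):
            return NotImplemented
        return (
            np.allclose(self.slices, other.slices)
            and np.allclose(self.pixel_spacing_mm, other.pixel_spacing_mm)
            and np.isclose(self.slice_thickness_mm, other.slice_thickness_mm)
            and np.isclose(self.slice_gap_mm, other.slice_gap_mm)
            and self.subject_id == other.subject_id
        )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_stack(stack: CineStack, path: str | Path) -> Path:
    """Write a stack as a NIfTI-1 volume plus a JSON metadata sidecar."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # NIfTI stores (i, j, k) = (row, col, slice); keep base->apex along k
    data = np.transpose(np.asarray(stack.slices, dtype=np.float32), (1, 2, 0))
    affine = np.diag(
        [
            stack.pixel_spacing_mm[0],
            stack.pixel_spacing_mm[1],
            stack.slice_interval_mm,
            1.0,
        ]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(
        (stack.pixel_spacing_mm[0], stack.pixel_spacing_mm[1], stack.slice_interval_mm)
    )
    nib.save(img, str(path))
    meta = {
        "subject_id": stack.subject_id,
        "slice_thickness_mm": stack.slice_thickness_mm,
        "slice_gap_mm": stack.slice_gap_mm,
        "frame_label": stack.frame_label,
        "slice_order": "base_to_apex",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _load_nifti_stack(path: Path) -> CineStack:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4:  # single-frame 4-D volume
        if data.shape[3] != 1:
            raise StackLoadError(
                "4-D cine NIfTI given; select the end-diastolic frame first"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise StackLoadError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms[:2]):
        raise StackLoadError("NIfTI header carries no positive pixel spacing")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    thickness = float(meta.get("slice_thickness_mm", zooms[2]))
    gap = float(meta.get("slice_gap_mm", 0.0))
    return CineStack(
        slices=np.transpose(data, (2, 0, 1)),
        pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=thickness,
        slice_gap_mm=gap,
        frame_label=meta.get("frame_label", "end-diastole (declared)"),
        subject_id=meta.get("subject_id", path.name.split(".")[0]),
    )


def _load_dicom_stack(path: Path) -> CineStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM clutter in the directory
    if not datasets:
        raise StackLoadError(f"no readable DICOM files under {path}")

    def location(ds) -> float:
        if hasattr(ds, "SliceLocation"):
            return float(ds.SliceLocation)
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        raise StackLoadError("DICOM frame lacks slice-location metadata")

    datasets.sort(key=location)
    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise StackLoadError(f"mixed slice dimensions {shapes} in series")
    spacings = {tuple(float(v) for v in getattr(ds, "PixelSpacing", ())) for ds in datasets}
    if spacings == {()}:
        raise StackLoadError("DICOM series lacks PixelSpacing")
    if len(spacings) != 1:
        raise StackLoadError(f"mixed pixel spacings {spacings} in series")
    spacing = spacings.pop()
    ds0 = datasets[0]
    thickness = float(getattr(ds0, "SliceThickness", 0.0) or 0.0)
    if thickness <= 0:
        raise StackLoadError("DICOM series lacks SliceThickness")
    locs = np.array([location(ds) for ds in datasets])
    gap = 0.0
    if len(locs) > 1:
        interval = float(np.median(np.abs(np.diff(locs))))
        gap = max(0.0, interval - thickness)
    data = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    return CineStack(
        slices=data,
        pixel_spacing_mm=(spacing[0], spacing[1]),
        slice_thickness_mm=thickness,
        slice_gap_mm=gap,
        frame_label="end-diastole (single-frame series)",
        subject_id=str(getattr(ds0, "PatientID", "anonymous")),
        )


def load_stack(
    path: str | Path,
    format_hint: str | None = None,
    apex_first: bool = False,
) -> CineStack:
    """Load a cine stack from a NIfTI file or a DICOM series directory.

    Slices are sorted base->apex: by ascending slice location for DICOM,
    by declared axis orientation for NIfTI.  Set ``apex_first=True`` when
    the on-disk order runs apex->base; the order is never guessed from
    pixel content.
    """
    path = Path(path)
    if not path.exists():
        raise StackLoadError(f"no such path: {path}")
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise StackLoadError(f"cannot infer format of {path}")
    if fmt == "nifti":
        stack = _load_nifti_stack(path)
    elif fmt == "dicom":
        stack = _load_dicom_stack(path)
    else:
        raise StackLoadError(f"unknown format hint {fmt!r}")
    if apex_first:
        stack = replace(stack, slices=stack.slices[::-1].copy())
    return stack


def load_mask_stack(path: str | Path) -> np.ndarray:
    """Load a binary mask stack from NIfTI (any nonzero = foreground) or PNG."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).get_fdata())
        if data.ndim == 2:
            data = data[..., None]
        return np.transpose(data > 0, (2, 0, 1))
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return (np.asarray(iio.imread(str(path))) > 127)[None, ...]
    raise StackLoadError(f"unsupported mask format: {path}")


def write_results(
    fractal_result,
    indices,
    path: str | Path,
    subject_id: str = "anonymous",
    extra: dict | None = None,
) -> Path:
    """Write one subject's scalars plus the per-slice table as JSON.

    Excluded slices (including the automatically excluded most apical
    slice) stay in the per-slice table with their flag and reason, but are
    absent from every aggregate.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "subject_id": subject_id,
    }
    if fractal_result is not None:
        payload["fractal"] = fractal_result.to_dict()
    if indices is not None:
        payload["indices"] = indices.to_dict() if hasattr(indices, "to_dict") else dict(indices)
    if extra:
        payload.update(extra)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=_default, allow_nan=True))
    return path


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_overlay_png(
    image: np.ndarray, edge_map: np.ndarray, path: str | Path
) -> Path:
    """QC overlay: grayscale slice with the detected border burned in red."""
    import imageio.v3 as iio

    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    gray = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[np.asarray(edge_map, dtype=bool)] = (1.0, 0.0, 0.0)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(str(path), (rgb * 255).astype(np.uint8))
    return path


COHORT_COLUMNS = [
    "subject_id",
    "group",
    "global_fd",
    "max_fd",
    "third_max_basal",
    "third_max_mid",
    "third_max_apical",
    "n_included",
    "petersen_ratio",
    "petersen_class",
    "jacquier_fraction",
    "jacquier_class",
]


def write_cohort_csv(rows: Sequence[dict], path: str | Path):
    """One CSV row per subject; an empty cohort still yields a valid header."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(rows), columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)
    return df
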