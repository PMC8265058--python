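"""Layer-ratio and mass-fraction trabeculation indices.

Two established CMR criteria complement the fractal score:

* the noncompacted/compacted (NC/C) layer-thickness ratio measured in
  diastole — the subject is classified LVNC when the largest ratio is
  >= 2.3, hyper-trabeculated when 1.8 <= ratio < 2.3, normal below 1.8;
* the trabecular mass fraction — noncompacted mass as a share of total
  LV mass, computed by subtracting the compacted mass from the total;
  a fraction strictly above 20% is diagnostic for LVNC.

Thickness pairs come from phantom ground truth or manual entry; mask
stacks come from the generator or from segmentation exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TrabeculationIndices",
    "petersen_ratio",
    "jacquier_fraction",
    "classify_petersen",
    "classify_jacquier",
    "mask_stack_mass_g",
    "PETERSEN_LVNC_THRESHOLD",
    "PETERSEN_HYPER_THRESHOLD",
    "JACQUIER_LVNC_THRESHOLD",
    "MYOCARDIAL_DENSITY_G_PER_ML",
]

PETERSEN_LVNC_THRESHOLD = 2.3    # ratio >= 2.3 -> lvnc (inclusive)
PETERSEN_HYPER_THRESHOLD = 1.8   # 1.8 <= ratio < 2.3 -> hypertrabeculated
JACQUIER_LVNC_THRESHOLD = 0.20   # fraction > 20% -> lvnc (strict)
MYOCARDIAL_DENSITY_G_PER_ML = 1.05  # standard myocardial tissue density


class MeasurementError(ValueError):
    """Invalid thickness or mask measurements."""


@dataclass(frozen=True)
class TrabeculationIndices:
    petersen_ratio: float | None = None
    petersen_class: str | None = None
    jacquier_fraction: float | None = None
    jacquier_class: str | None = None
    total_mass_g: float | None = None
    compacted_mass_g: float | None = None

    def to_dict(self) -> dict:
        return {
            "petersen_ratio": self.petersen_ratio,
            "petersen_class": self.petersen_class,
            "jacquier_fraction": self.jacquier_fraction,
            "jacquier_class": self.jacquier_class,
            "total_mass_g": self.total_mass_g,
            "compacted_mass_g": self.compacted_mass_g,
        }


def classify_petersen(
    ratio: float,
    lvnc_threshold: float = PETERSEN_LVNC_THRESHOLD,
    hyper_threshold: float = PETERSEN_HYPER_THRESHOLD,
) -> str:
    """NC/C ratio class: >= 2.3 lvnc, >= 1.8 hypertrabeculated, else normal."""
    if ratio >= lvnc_threshold:
        return "lvnc"
    if ratio >= hyper_threshold:
        return "hypertrabeculated"
    return "normal"


def classify_jacquier(
    fraction: float, threshold: float = JACQUIER_LVNC_THRESHOLD
) -> str:
    """Mass-fraction class: strictly above 20% is lvnc."""
    return "lvnc" if fraction > threshold else "normal"


def petersen_ratio(
    nc_thickness_mm: Sequence[float],
    c_thickness_mm: Sequence[float],
    lvnc_threshold: float = PETERSEN_LVNC_THRESHOLD,
    hyper_threshold: float = PETERSEN_HYPER_THRESHOLD,
) -> tuple[float, str]:
    """Largest diastolic NC/C layer ratio over paired measurements.

    Several measurements are typically made per case; the highest
    obtained ratio is recorded and classified.
    """
    nc = np.asarray(nc_thickness_mm, dtype=float)
    c = np.asarray(c_thickness_mm, dtype=float)
    if nc.shape != c.shape or nc.size == 0:
        raise MeasurementError("need >= 1 paired NC/C thickness measurements")
    if np.any(c <= 0):
        raise MeasurementError("compacted thickness must be positive")
    if np.any(nc < 0):
        raise MeasurementError("noncompacted thickness cannot be negative")
    ratio = float(np.max(nc / c))
    return ratio, classify_petersen(ratio, lvnc_threshold, hyper_threshold)


def mask_stack_mass_g(
    mask_stack: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    slice_thickness_mm: float,
    slice_gap_mm: float = 0.0,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> float:
    """Tissue mass of a binary mask stack.

    Per-slice area times the centre-to-centre slice interval (thickness +
    gap: the contiguous-coverage convention for gapped acquisitions)
    times density.  1 mL = 1000 mm^3.
    """
    mask_stack = np.asarray(mask_stack).astype(bool)
    if mask_stack.ndim != 3:
        raise MeasurementError(f"mask stack must be 3-D, got {mask_stack.shape}")
    pixel_area_mm2 = float(pixel_spacing_mm[0]) * float(pixel_spacing_mm[1])
    volume_mm3 = mask_stack.sum() * pixel_area_mm2 * (
        slice_thickness_mm + slice_gap_mm
    )
    return float(volume_mm3 / 1000.0 * density_g_per_ml)


def jacquier_fraction(
    total_mask_stack: np.ndarray,
    compacted_mask_stack: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    slice_thickness_mm: float,
    slice_gap_mm: float = 0.0,
    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
    threshold: float = JACQUIER_LVNC_THRESHOLD,
) -> tuple[float, str]:
    """Noncompacted mass fraction of total LV mass, and its class.

    Noncompacted mass is total minus compacted; the compacted mask must
    be a per-slice subset of the total myocardium mask.
    """
    total = np.asarray(total_mask_stack).astype(bool)
    compacted = np.asarray(compacted_mask_stack).astype(bool)
    if total.shape != compacted.shape:
        raise MeasurementError("total and compacted mask stacks differ in shape")
    if np.any(compacted & ~total):
        raise MeasurementError("compacted mask extends outside the total mask")
    args = (pixel_spacing_mm, slice_thickness_mm, slice_gap_mm, density_g_per_ml)
    total_mass = mask_stack_mass_g(total, *args)
    compacted_mass = mask_stack_mass_g(compacted, *args)
    if total_mass <= 0:
        raise MeasurementError("total mass is zero")
    fraction = 1.0 - compacted_mass / total_mass
    return float(fraction), classify_jacquier(fraction, threshold)
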