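"""Expansion-factor calibration, measurement correction, nucleus statistics,
and the antibody linkage-error model.

All corrected outputs are nm; the nucleus cross-section statistic is um.
Inputs may be given in um via the ``unit`` argument where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border

from exmquant import profiles as _profiles

__all__ = [
    "RulerSpec",
    "CalibrationResult",
    "LinkageModel",
    "NucleusMeasurement",
    "RULERS",
    "expansion_factor",
    "correct_measurement",
    "segment_nuclei",
    "ncs",
    "linkage_apparent_diameter",
    "ring_diameter",
    "RingError",
]


class RingError(ValueError):
    """No discernible ring in the image / radial profile."""


@dataclass(frozen=True)
class RulerSpec:
    """A reference structure of known physical size used to calibrate the
    expansion factor."""

    name: str
    reference_dim_nm: float
    dimension_kind: str = "diameter"  # diameter | length | separation
    measurement_convention: str = "peak_to_peak"  # peak_to_peak | half_max

    def __post_init__(self) -> None:
        if self.reference_dim_nm <= 0:
            raise ValueError("reference_dim_nm must be positive")
        if self.dimension_kind not in ("diameter", "length", "separation"):
            raise ValueError(f"unknown dimension_kind {self.dimension_kind!r}")
        if self.measurement_convention not in ("peak_to_peak", "half_max"):
            raise ValueError(
                f"unknown measurement_convention {self.measurement_convention!r}"
            )


#: Built-in ruler presets (reference dimensions in nm).
RULERS: dict[str, RulerSpec] = {
    "nup96": RulerSpec("nup96", 107.0, "diameter", "peak_to_peak"),
    "conoid": RulerSpec("conoid", 380.0, "diameter", "peak_to_peak"),
    "cr-bb": RulerSpec("cr-bb", 225.0, "diameter", "peak_to_peak"),
    "retina-bb": RulerSpec("retina-bb", 230.0, "diameter", "half_max"),
}


@dataclass(frozen=True)
class CalibrationResult:
    expansion_factor: float
    ruler: RulerSpec
    expanded_measurement_nm: float
    n_measured: int = 1

    def __post_init__(self) -> None:
        if self.expansion_factor <= 0:
            raise ValueError("expansion_factor must be positive")


@dataclass(frozen=True)
class LinkageModel:
    """Apparent-diameter model for an antibody-decorated structure.

    The antibody stack adds ``linkage_nm`` on each side. Pre-expansion labels
    scale with the gel; post-expansion labels are applied in the expanded
    frame and do not scale, so in corrected units their contribution shrinks
    by 1/expansion_factor.
    """

    d_true_nm: float
    linkage_nm: float
    expansion_factor: float = 1.0
    labeling_mode: str = "pre_expansion"  # pre_expansion | post_expansion

    def __post_init__(self) -> None:
        if min(self.d_true_nm, self.linkage_nm, self.expansion_factor) <= 0:
            raise ValueError("all model parameters must be positive")
        if self.labeling_mode not in ("pre_expansion", "post_expansion"):
            raise ValueError(f"unknown labeling_mode {self.labeling_mode!r}")


@dataclass(frozen=True)
class NucleusMeasurement:
    area_um2: float
    gel_expansion: float

    @property
    def ncs_um(self) -> float:
        return ncs(self.area_um2, self.gel_expansion)


def _to_nm(value: float, unit: str) -> float:
    if unit == "nm":
        return float(value)
    if unit in ("um", "µm"):
        return float(value) * 1000.0
    raise ValueError(f"unknown unit {unit!r}: declare 'nm' or 'um'")


def expansion_factor(
    expanded_dim: float,
    ruler: RulerSpec | str,
    unit: str = "nm",
    n_measured: int = 1,
) -> CalibrationResult:
    """Expansion factor = expanded dimension / ruler reference dimension."""
    if isinstance(ruler, str):
        ruler = RULERS[ruler]
    expanded_nm = _to_nm(expanded_dim, unit)
    if expanded_nm <= 0:
        raise ValueError("expanded_dim must be positive")
    return CalibrationResult(
        expanded_nm / ruler.reference_dim_nm, ruler, expanded_nm, n_measured
    )


def correct_measurement(expanded_value_nm: float, calibration: CalibrationResult | float) -> float:
    """Divide an expanded measurement (nm) by the calibrated expansion factor."""
    ef = (
        calibration.expansion_factor
        if isinstance(calibration, CalibrationResult)
        else float(calibration)
    )
    if ef <= 0:
        raise ValueError("expansion factor must be positive")
    return expanded_value_nm / ef


def segment_nuclei(
    image: np.ndarray,
    pixel_size_nm: float,
    threshold_spec="otsu",
    min_area_um2: float = 1.0,
    exclude_border: bool = True,
    fill_holes: bool = True,
) -> list[float]:
    """Binarize, label connected components, return their areas in um^2.

    Components touching the image border are excluded by default (their area
    is censored). Returns an empty list when nothing passes the filters.
    """
    image = np.asarray(image, dtype=float)
    if isinstance(threshold_spec, str) and threshold_spec == "otsu":
        thr = float(threshold_otsu(image))
    else:
        thr = float(threshold_spec)
    mask = image > thr
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if exclude_border:
        mask = clear_border(mask)
    labeled = sk_label(mask)
    px_area_um2 = (pixel_size_nm / 1000.0) ** 2
    areas = [
        p.area * px_area_um2
        for p in regionprops(labeled)
        if p.area * px_area_um2 >= min_area_um2
    ]
    return areas


def ncs(area_um2: float, gel_expansion: float) -> float:
    """Nucleus cross-section statistic: sqrt(area) / gel expansion factor (um)."""
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    if gel_expansion <= 0:
        raise ValueError("gel_expansion must be positive")
    return math.sqrt(area_um2) / gel_expansion


def linkage_apparent_diameter(model: LinkageModel) -> float:
    """Corrected apparent diameter (nm) of the labeled structure.

    pre_expansion:  d_true + 2 * linkage (independent of the expansion factor)
    post_expansion: d_true + 2 * linkage / expansion_factor
    """
    if model.labeling_mode == "pre_expansion":
        return model.d_true_nm + 2 * model.linkage_nm
    return model.d_true_nm + 2 * model.linkage_nm / model.expansion_factor


def radial_intensity_profile(
    image: np.ndarray,
    pixel_size_nm: float,
    center_px: Sequence[float] | None = None,
    n_angle_bins: int = 360,
) -> tuple[np.ndarray, np.ndarray]:
    """Angularly averaged intensity vs radius (nm) about the ring center.

    The center defaults to the intensity-weighted centroid of the image.
    """
    image = np.asarray(image, dtype=float)
    if center_px is None:
        total = image.sum()
        if total <= 0:
            raise RingError("image has no intensity")
        ii, jj = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        center_px = (float((jj * image).sum() / total), float((ii * image).sum() / total))
    polar = _profiles.polar_transform(
        image, center_px, pixel_size_nm, n_angle_bins=n_angle_bins
    )
    return polar.radius_bins, polar.intensity.mean(axis=0)


def ring_diameter(
    image: np.ndarray,
    pixel_size_nm: float,
    convention: str = "peak_to_peak",
    center_px: Sequence[float] | None = None,
) -> float:
    """Ring diameter (nm) from the angularly averaged radial profile.

    peak_to_peak: twice the (parabolically refined) radius of the radial
    maximum. half_max: twice the outer radius where the profile falls to 50%
    of its maximum (outer width of the diametric profile).
    """
    radius_nm, prof = radial_intensity_profile(image, pixel_size_nm, center_px)
    i_peak = int(np.argmax(prof))
    if i_peak == 0 or i_peak == prof.size - 1:
        raise RingError("no discernible ring: radial profile is monotone")
    if convention == "peak_to_peak":
        r = _profiles._parabolic_refine(radius_nm, prof, i_peak)
        return 2.0 * r
    if convention == "half_max":
        half = 0.5 * prof[i_peak]
        j = i_peak
        while j + 1 < prof.size and prof[j + 1] > half:
            j += 1
        if j + 1 >= prof.size:
            raise RingError("outer half-maximum crossing not found")
        frac = (prof[j] - half) / (prof[j] - prof[j + 1])
        r = radius_nm[j] + frac * (radius_nm[j + 1] - radius_nm[j])
        return 2.0 * float(r)
    raise ValueError(f"unknown convention {convention!r}")
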