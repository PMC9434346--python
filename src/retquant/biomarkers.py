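"""Quantification of the 12 imaging biomarkers.

Per eye and visit: EZ/ELM length rates (proportion of 16-px clips where the
layer is detected), area and maximum horizontal diameter of each lesion
class, and mean intensity of SHRM and PED on the normalized image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .synthetic import (AnnotationSet, BScanImage, FEATURE_NAMES,
                        LABEL_CODES, LESION_CLASSES)

INTENSITY_CLASSES = ("SHRM", "PED")


@dataclass(frozen=True)
class BiomarkerVector:
    """The 12 scalar features of one eye at one visit."""

    ez_length_rate: float
    elm_length_rate: float
    irf_area_mm2: float
    irf_max_diameter_mm: float
    srf_area_mm2: float
    srf_max_diameter_mm: float
    shrm_area_mm2: float
    shrm_max_diameter_mm: float
    ped_area_mm2: float
    ped_max_diameter_mm: float
    shrm_mean_intensity: float   # NaN = missing (empty class)
    ped_mean_intensity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _class_binary(mask: np.ndarray, lesion_class: str) -> np.ndarray:
    if lesion_class not in LESION_CLASSES:
        raise ValueError(f"unknown lesion class {lesion_class!r}")
    return np.asarray(mask) == LABEL_CODES[lesion_class]


def layer_length_rate(presence: np.ndarray) -> float:
    """Proportion of clips in which the layer was detected."""
    presence = np.asarray(presence)
    if presence.size == 0:
        raise ValueError("empty presence vector")
    return float(np.count_nonzero(presence)) / presence.size


def region_area(mask: np.ndarray, lesion_class: str,
                pixel_size_mm: float) -> float:
    """Total class area in mm^2, summed over all connected components."""
    return float(_class_binary(mask, lesion_class).sum()) * pixel_size_mm ** 2


def region_max_diameter(mask: np.ndarray, lesion_class: str,
                        pixel_size_mm: float) -> float:
    """Largest horizontal extent (inclusive column span) of any connected
    component of the class, in mm; 0 when the class is empty."""
    binary = _class_binary(mask, lesion_class)
    if not binary.any():
        return 0.0
    labeled = measure.label(binary, connectivity=2)
    widest = max(r.bbox[3] - r.bbox[1] for r in measure.regionprops(labeled))
    return widest * pixel_size_mm


def region_mean_intensity(img: BScanImage | np.ndarray, mask: np.ndarray,
                          lesion_class: str) -> float:
    """Mean normalized intensity over class pixels; NaN when class empty."""
    if lesion_class not in INTENSITY_CLASSES:
        raise ValueError(
            f"mean intensity is defined for {INTENSITY_CLASSES}, "
            f"got {lesion_class!r}")
    data = img.intensity if isinstance(img, BScanImage) else np.asarray(img)
    binary = _class_binary(mask, lesion_class)
    if not binary.any():
        return math.nan
    return float(data[binary].mean())


def extract_biomarkers(img: BScanImage | np.ndarray,
                       lesion_mask: np.ndarray,
                       ez_presence: np.ndarray,
                       elm_presence: np.ndarray,
                       pixel_size_mm: float | None = None) -> BiomarkerVector:
    """Assemble the full 12-feature vector from detections and segmentation."""
    data = img.intensity if isinstance(img, BScanImage) else np.asarray(img)
    if pixel_size_mm is None:
        if not isinstance(img, BScanImage):
            raise ValueError("pixel_size_mm required for raw-array input")
        pixel_size_mm = img.pixel_size_mm
    lesion_mask = np.asarray(lesion_mask)
    if lesion_mask.shape != data.shape:
        raise ValueError(
            f"mask shape {lesion_mask.shape} != image shape {data.shape}")
    values: dict[str, float] = {
        "ez_length_rate": layer_length_rate(ez_presence),
        "elm_length_rate": layer_length_rate(elm_presence),
    }
    for cls in LESION_CLASSES:
        key = cls.lower()
        values[f"{key}_area_mm2"] = region_area(lesion_mask, cls, pixel_size_mm)
        values[f"{key}_max_diameter_mm"] = region_max_diameter(
            lesion_mask, cls, pixel_size_mm)
    for cls in INTENSITY_CLASSES:
        values[f"{cls.lower()}_mean_intensity"] = region_mean_intensity(
            data, lesion_mask, cls)
    return BiomarkerVector(**values)


def biomarkers_from_annotation(img: BScanImage, annotation: AnnotationSet
                               ) -> BiomarkerVector:
    """Round-trip helper: quantify directly from ground-truth annotation."""
    from .detection import clip_labels  # local import avoids cycle at import time

    return extract_biomarkers(
        img, annotation.lesion_mask,
        ez_presence=clip_labels(annotation, "ez"),
        elm_presence=clip_labels(annotation, "elm"),
        pixel_size_mm=img.pixel_size_mm)
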