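"""Seeded synthetic B-scan scenes, annotations and longitudinal cohorts.

Renders layered retina cross-sections (dark vitreous, medium retina, bright
RPE band, dim choroid) with thin bright EZ/ELM lines interrupted by seeded
gaps, rasterized lesions (IRF, SRF, SHRM, PED), multiplicative speckle, and
analytic ground-truth biomarkers. Longitudinal cohorts evolve lesion
trajectories per outcome class and label each eye via a planted rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

CLIP_WIDTH = 16

LESION_CLASSES = ("IRF", "SRF", "SHRM", "PED")
LABEL_CODES = {"background": 0, "IRF": 1, "SRF": 2, "SHRM": 3, "PED": 4}
VISITS = ("baseline", "month1", "month3", "month12")

FEATURE_NAMES = (
    "ez_length_rate",
    "elm_length_rate",
    "irf_area_mm2",
    "irf_max_diameter_mm",
    "srf_area_mm2",
    "srf_max_diameter_mm",
    "shrm_area_mm2",
    "shrm_max_diameter_mm",
    "ped_area_mm2",
    "ped_max_diameter_mm",
    "shrm_mean_intensity",
    "ped_mean_intensity",
)


class SceneValidationError(ValueError):
    """Raised when a scene or cohort spec violates an invariant."""


@dataclass(frozen=True)
class LesionSpec:
    lesion_class: str          # one of LESION_CLASSES
    shape: str                 # "ellipse" or "dome"
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]    # (row semi-axis, col semi-axis), pixels
    intensity: float             # rendered level in [0, 1]


@dataclass(frozen=True)
class SceneSpec:
    image_height: int = 256
    image_width: int = 1600
    retina_top: int | None = None
    retina_bottom: int | None = None
    ez_row: int | None = None
    elm_row: int | None = None
    ez_gap_fraction: float = 0.0
    elm_gap_fraction: float = 0.0
    lesion_specs: tuple[LesionSpec, ...] = ()
    speckle_sigma: float = 0.1
    pixel_size_mm: float = 8.0 / 1600.0

    def __post_init__(self):
        h = self.image_height
        if self.retina_top is None:
            object.__setattr__(self, "retina_top", round(0.30 * h))
        if self.retina_bottom is None:
            object.__setattr__(self, "retina_bottom", round(0.75 * h))
        if self.elm_row is None:
            object.__setattr__(self, "elm_row", round(0.62 * h))
        if self.ez_row is None:
            object.__setattr__(self, "ez_row", round(0.67 * h))

    @classmethod
    def desk(cls, **kw) -> "SceneSpec":
        """Desk-scale profile: 128x512 (32 clips), same clip width."""
        kw.setdefault("image_height", 128)
        kw.setdefault("image_width", 512)
        kw.setdefault("pixel_size_mm", 8.0 / 512.0)
        return cls(**kw)

    def validate(self) -> None:
        if self.image_height < 16:
            raise SceneValidationError("image_height too small")
        if self.image_width % CLIP_WIDTH != 0:
            raise SceneValidationError(
                f"image_width={self.image_width} not divisible by {CLIP_WIDTH}")
        for name in ("ez_gap_fraction", "elm_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SceneValidationError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.retina_top < self.retina_bottom < self.image_height:
            raise SceneValidationError(
                "retina_top/retina_bottom must satisfy "
                "0 <= top < bottom < height")
        for name in ("ez_row", "elm_row"):
            r = getattr(self, name)
            if not self.retina_top <= r <= self.retina_bottom:
                raise SceneValidationError(
                    f"{name}={r} outside retina [{self.retina_top}, "
                    f"{self.retina_bottom}]")
        if self.speckle_sigma < 0:
            raise SceneValidationError("speckle_sigma must be >= 0")
        if self.pixel_size_mm <= 0:
            raise SceneValidationError("pixel_size_mm must be > 0")
        for les in self.lesion_specs:
            if les.lesion_class not in LESION_CLASSES:
                raise SceneValidationError(
                    f"lesion_class={les.lesion_class!r} unknown")
            if les.shape not in ("ellipse", "dome"):
                raise SceneValidationError(f"shape={les.shape!r} unknown")
            if les.axes[0] <= 0 or les.axes[1] <= 0:
                raise SceneValidationError("lesion axes must be > 0")


@dataclass
class AnnotationSet:
    """Per-pixel lesion labels plus per-column EZ/ELM trace rows (NaN = gap)."""

    lesion_mask: np.ndarray   # (H, W) uint8, codes per LABEL_CODES
    ez_trace: np.ndarray      # (W,) float, row index or NaN
    elm_trace: np.ndarray     # (W,) float, row index or NaN


@dataclass
class GroundTruthFeatures:
    """Analytic biomarkers of one scene (pre-noise geometry)."""

    ez_length_rate: float
    elm_length_rate: float
    areas_mm2: dict[str, float]
    max_diameters_mm: dict[str, float]
    mean_intensities: dict[str, float]  # SHRM/PED; NaN when class empty

    def as_vector(self) -> dict[str, float]:
        return {
            "ez_length_rate": self.ez_length_rate,
            "elm_length_rate": self.elm_length_rate,
            "irf_area_mm2": self.areas_mm2["IRF"],
            "irf_max_diameter_mm": self.max_diameters_mm["IRF"],
            "srf_area_mm2": self.areas_mm2["SRF"],
            "srf_max_diameter_mm": self.max_diameters_mm["SRF"],
            "shrm_area_mm2": self.areas_mm2["SHRM"],
            "shrm_max_diameter_mm": self.max_diameters_mm["SHRM"],
            "ped_area_mm2": self.areas_mm2["PED"],
            "ped_max_diameter_mm": self.max_diameters_mm["PED"],
            "shrm_mean_intensity": self.mean_intensities["SHRM"],
            "ped_mean_intensity": self.mean_intensities["PED"],
        }


@dataclass
class BScanImage:
    intensity: np.ndarray     # (H, W) float32 in [0, 1]
    pixel_size_mm: float


@dataclass
class LongitudinalRecord:
    eye_id: str
    visits: dict[str, tuple[BScanImage, AnnotationSet, GroundTruthFeatures]]
    label: int


def _line_trace(width: int, row: int, gap_fraction: float,
                rng: np.random.Generator) -> np.ndarray:
    """Row trace with one contiguous seeded gap interval."""
    trace = np.full(width, float(row))
    gap_len = int(round(gap_fraction * width))
    if gap_len > 0:
        start = int(rng.integers(0, width - gap_len + 1)) if gap_len < width else 0
        trace[start:start + gap_len] = np.nan
    return trace


def _rasterize_lesion(les: LesionSpec, height: int, width: int) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width]
    cr, ccen = les.center
    ar, ac = les.axes
    inside = ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0
    if les.shape == "dome":
        inside &= rr <= cr   # upper half-ellipse resting on its base row
    return inside


def _clip_presence_rate(trace: np.ndarray) -> float:
    """Fraction of 16-px clips in which the trace is present in >=1 column."""
    present = ~np.isnan(trace)
    n_clips = trace.size // CLIP_WIDTH
    return float(present.reshape(n_clips, CLIP_WIDTH).any(axis=1).mean())


def _ground_truth(mask: np.ndarray, clean: np.ndarray,
                  ez_trace: np.ndarray, elm_trace: np.ndarray,
                  pixel_size_mm: float) -> GroundTruthFeatures:
    areas, diams, intens = {}, {}, {}
    for cls in LESION_CLASSES:
        binary = mask == LABEL_CODES[cls]
        areas[cls] = float(binary.sum()) * pixel_size_mm ** 2
        if binary.any():
            labeled, n = ndimage.label(binary)
            widest = 0
            for sl in ndimage.find_objects(labeled):
                widest = max(widest, sl[1].stop - sl[1].start)
            diams[cls] = widest * pixel_size_mm
        else:
            diams[cls] = 0.0
        if cls in ("SHRM", "PED"):
            intens[cls] = float(clean[binary].mean()) if binary.any() else float("nan")
    return GroundTruthFeatures(
        ez_length_rate=_clip_presence_rate(ez_trace),
        elm_length_rate=_clip_presence_rate(elm_trace),
        areas_mm2=areas,
        max_diameters_mm=diams,
        mean_intensities=intens,
    )


# rendered intensity levels (pre-noise)
_LEVELS = {"vitreous": 0.05, "retina": 0.35, "rpe": 0.85, "choroid": 0.20,
           "line": 0.95}


def generate_scene(spec: SceneSpec, seed: int
                   ) -> tuple[BScanImage, AnnotationSet, GroundTruthFeatures]:
    """Render one B-scan with exactly consistent annotation and ground truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.image_height, spec.image_width

    img = np.full((h, w), _LEVELS["vitreous"], dtype=np.float32)
    img[spec.retina_top:spec.retina_bottom + 1] = _LEVELS["retina"]
    rpe_thick = max(2, h // 42)
    img[spec.retina_bottom - rpe_thick + 1:spec.retina_bottom + 1] = _LEVELS["rpe"]
    img[spec.retina_bottom + 1:] = _LEVELS["choroid"]

    mask = np.zeros((h, w), dtype=np.uint8)
    for les in spec.lesion_specs:
        region = _rasterize_lesion(les, h, w)
        mask[region] = LABEL_CODES[les.lesion_class]
        img[region] = les.intensity

    line_thick = int(np.clip(h // 100, 1, 3))
    ez_trace = _line_trace(w, spec.ez_row, spec.ez_gap_fraction, rng)
    elm_trace = _line_trace(w, spec.elm_row, spec.elm_gap_fraction, rng)
    for trace in (ez_trace, elm_trace):
        cols = np.flatnonzero(~np.isnan(trace))
        if cols.size:
            row = int(trace[cols[0]])
            for r in range(row, min(row + line_thick, h)):
                draw = cols[mask[r, cols] == 0]   # keep lesions un-overwritten
                img[r, draw] = _LEVELS["line"]

    annotation = AnnotationSet(lesion_mask=mask, ez_trace=ez_trace,
                               elm_trace=elm_trace)
    truth = _ground_truth(mask, img, ez_trace, elm_trace, spec.pixel_size_mm)

    if spec.speckle_sigma > 0:
        img = img * (1.0 + spec.speckle_sigma
                     * rng.standard_normal((h, w)).astype(np.float32))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return BScanImage(img, spec.pixel_size_mm), annotation, truth


# ---------------------------------------------------------------------------
# Longitudinal cohorts with a planted outcome rule
# ---------------------------------------------------------------------------

def default_outcome_rule(features: dict[str, GroundTruthFeatures]) -> int:
    """Planted three-class rule on feature trajectories.

    2 (cured): fluid areas reach 0 by month 3 and SHRM/PED reach 0 by month 12.
    0 (stable): fluid areas reach 0 by month 3 but SHRM or PED persists.
    1 (PDA): otherwise (persistent fluid; EZ/ELM integrity depressed).
    """
    m3, m12 = features["month3"], features["month12"]
    fluid_gone = all(
        f.areas_mm2["IRF"] == 0 and f.areas_mm2["SRF"] == 0
        for f in (m3, m12))
    lesions_gone = m12.areas_mm2["SHRM"] == 0 and m12.areas_mm2["PED"] == 0
    if fluid_gone and lesions_gone:
        return 2
    if fluid_gone:
        return 0
    return 1


# per-class, per-visit area-scale multipliers for each lesion kind
_TRAJECTORIES = {
    # label: {lesion group: (baseline, month1, month3, month12)}
    0: {"fluid": (1.0, 0.5, 0.0, 0.0), "solid": (1.0, 0.9, 0.85, 0.8)},
    1: {"fluid": (1.0, 0.9, 0.8, 0.85), "solid": (1.0, 1.0, 0.95, 1.0)},
    2: {"fluid": (1.0, 0.4, 0.0, 0.0), "solid": (1.0, 0.6, 0.3, 0.0)},
}
# EZ/ELM gap-fraction trajectories (class 1 keeps integrity depressed)
_GAP_TRAJECTORIES = {
    0: (0.20, 0.15, 0.10, 0.08),
    1: (0.35, 0.40, 0.45, 0.45),
    2: (0.15, 0.10, 0.05, 0.0),
}


def _eye_lesion_template(spec: SceneSpec, rng: np.random.Generator
                         ) -> list[tuple[str, str, tuple[float, float],
                                         tuple[float, float], float]]:
    """Sample per-eye baseline lesion geometry (class, shape, center, axes, level)."""
    h, w = spec.image_height, spec.image_width
    jitter = lambda lo, hi: float(rng.uniform(lo, hi))
    mid = (spec.retina_top + spec.elm_row) / 2
    return [
        ("IRF", "ellipse",
         (jitter(mid - 0.04 * h, mid + 0.04 * h), jitter(0.2 * w, 0.4 * w)),
         (jitter(0.04, 0.07) * h, jitter(0.03, 0.06) * w), 0.08),
        ("SRF", "ellipse",
         (jitter(spec.ez_row + 2, spec.retina_bottom - 4), jitter(0.55 * w, 0.7 * w)),
         (jitter(0.025, 0.045) * h, jitter(0.04, 0.07) * w), 0.10),
        ("SHRM", "ellipse",
         (jitter(spec.ez_row, spec.retina_bottom - 3), jitter(0.75 * w, 0.88 * w)),
         (jitter(0.02, 0.04) * h, jitter(0.025, 0.05) * w), 0.80),
        ("PED", "dome",
         (float(spec.retina_bottom), jitter(0.35 * w, 0.55 * w)),
         (jitter(0.05, 0.09) * h, jitter(0.05, 0.09) * w), 0.70),
    ]


def _visit_spec(spec: SceneSpec, template, label: int, visit_idx: int,
                gap_jitter: float) -> SceneSpec:
    lesions = []
    for cls, shape, center, axes, level in template:
        group = "fluid" if cls in ("IRF", "SRF") else "solid"
        scale = _TRAJECTORIES[label][group][visit_idx]
        if scale <= 0:
            continue
        s = float(np.sqrt(scale))           # area scales linearly with `scale`
        lesions.append(LesionSpec(cls, shape, center,
                                  (axes[0] * s, axes[1] * s), level))
    gap = float(np.clip(_GAP_TRAJECTORIES[label][visit_idx] + gap_jitter, 0, 0.6))
    return replace(spec, lesion_specs=tuple(lesions),
                   ez_gap_fraction=gap, elm_gap_fraction=gap)


def generate_cohort(n_eyes: int,
                    outcome_model: Callable[[dict], int] = default_outcome_rule,
                    seed: int = 0,
                    scene_spec: SceneSpec | None = None,
                    class_weights: Sequence[float] = (0.45, 0.33, 0.22),
                    ) -> list[LongitudinalRecord]:
    """Generate `n_eyes` longitudinal records with a planted outcome rule.

    Lesion trajectories are drawn per intended class; the emitted label is
    whatever `outcome_model` assigns to the realised feature trajectories.
    """
    if n_eyes < 1:
        raise SceneValidationError(f"n_eyes={n_eyes} must be >= 1")
    spec = scene_spec if scene_spec is not None else SceneSpec.desk()
    spec.validate()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_eyes):
        intended = int(rng.choice(3, p=np.asarray(class_weights)
                                  / np.sum(class_weights)))
        template = _eye_lesion_template(spec, rng)
        gap_jitter = float(rng.uniform(-0.04, 0.04))
        visits = {}
        feats = {}
        for vi, visit in enumerate(VISITS):
            vspec = _visit_spec(spec, template, intended, vi, gap_jitter)
            scene_seed = int(rng.integers(0, 2**31 - 1))
            img, ann, truth = generate_scene(vspec, scene_seed)
            visits[visit] = (img, ann, truth)
            feats[visit] = truth
        label = outcome_model(feats)
        records.append(LongitudinalRecord(eye_id=f"eye{i:04d}",
                                          visits=visits, label=label))
    labels = {r.label for r in records}
    if len(labels) == 1:
        warnings.warn(f"degenerate outcome rule: every eye labelled "
                      f"{labels.pop()}", stacklevel=2)
    return records


def cohort_feature_table(records: Sequence[LongitudinalRecord]
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Long-format feature table (one row per eye-visit) and per-eye labels."""
    rows = []
    for rec in records:
        for visit, (_img, _ann, truth) in rec.visits.items():
            row = {"eye_id": rec.eye_id, "visit": visit}
            row.update(truth.as_vector())
            rows.append(row)
    table = pd.DataFrame(rows, columns=["eye_id", "visit", *FEATURE_NAMES])
    labels = pd.Series({r.eye_id: r.label for r in records}, name="label")
    return table, labels
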