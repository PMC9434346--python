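"""ROI cropping, resizing, min-max normalization and training augmentation."""

from __future__ import annotations

import logging
import warnings

import numpy as np
from skimage.transform import resize

from .synthetic import BScanImage, CLIP_WIDTH

logger = logging.getLogger(__name__)

DEFAULT_TARGET = (256, 1600)


def crop_and_resize(raw: np.ndarray,
                    roi: tuple[int, int, int, int] | str = "auto",
                    target_height: int = DEFAULT_TARGET[0],
                    target_width: int = DEFAULT_TARGET[1],
                    pixel_size_mm: float = 8.0 / 1600.0) -> BScanImage:
    """Crop `roi` = (top, left, height, width) out of `raw` and resize.

    Bilinear interpolation; aspect distortion is accepted. "auto" uses the
    full frame. Target width must stay divisible by the clip width.
    """
    raw = np.asarray(raw, dtype=np.float32)
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError("raw image must be a non-empty 2-D array")
    if target_width % CLIP_WIDTH != 0:
        raise ValueError(
            f"target_width={target_width} not divisible by {CLIP_WIDTH}")
    if roi == "auto":
        crop = raw
    else:
        top, left, height, width = roi
        if (top < 0 or left < 0 or height <= 0 or width <= 0
                or top + height > raw.shape[0] or left + width > raw.shape[1]):
            raise ValueError(f"roi {roi} outside raw bounds {raw.shape}")
        crop = raw[top:top + height, left:left + width]
    out = resize(crop, (target_height, target_width), order=1,
                 anti_aliasing=False, preserve_range=True).astype(np.float32)
    return BScanImage(out, pixel_size_mm)


def minmax_normalize(img: BScanImage | np.ndarray) -> BScanImage:
    """(x - min) / (max - min); constant input maps to zeros with a warning."""
    if isinstance(img, BScanImage):
        data, px = img.intensity, img.pixel_size_mm
    else:
        data, px = np.asarray(img, dtype=np.float32), float("nan")
    if data.size == 0:
        raise ValueError("empty image")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        logger.warning("constant image: min-max normalization yields zeros")
        warnings.warn("constant image normalized to zeros", stacklevel=2)
        return BScanImage(np.zeros_like(data, dtype=np.float32), px)
    return BScanImage(((data - lo) / (hi - lo)).astype(np.float32), px)


def augment(img: np.ndarray, mask: np.ndarray | None,
            traces: dict[str, np.ndarray] | None, seed: int, *,
            flip_p: float = 0.5, crop_scale_min: float = 0.9,
            shift_max: float = 0.1
            ) -> tuple[np.ndarray, np.ndarray | None, dict | None]:
    """Seeded flip / crop-and-resize / intensity-shift augmentation.

    The same geometric transform is applied to image, mask (nearest
    neighbour) and traces; the intensity shift touches only the image.
    """
    img = np.asarray(img, dtype=np.float32)
    h, w = img.shape
    if mask is not None and mask.shape != img.shape:
        raise ValueError("mask shape differs from image shape")
    if traces is not None:
        for name, tr in traces.items():
            if tr.shape != (w,):
                raise ValueError(f"trace {name!r} length differs from width")
    rng = np.random.default_rng(seed)

    flip = rng.random() < flip_p
    scale = float(rng.uniform(crop_scale_min, 1.0))
    ch, cw = max(1, round(scale * h)), max(1, round(scale * w))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    shift = float(rng.uniform(-shift_max, shift_max))

    def geom_img(a: np.ndarray, order: int) -> np.ndarray:
        if flip:
            a = a[:, ::-1]
        a = a[top:top + ch, left:left + cw]
        return resize(a, (h, w), order=order, anti_aliasing=False,
                      preserve_range=True)

    out_img = np.clip(geom_img(img, 1) + shift, 0.0, 1.0).astype(np.float32)
    out_mask = None
    if mask is not None:
        out_mask = geom_img(mask.astype(np.float32), 0).astype(mask.dtype)
    out_traces = None
    if traces is not None:
        out_traces = {}
        row_scale = h / ch
        for name, tr in traces.items():
            t = tr[::-1].copy() if flip else tr.copy()
            t = t[left:left + cw]
            t = (t - top) * row_scale
            t[(t < 0) | (t > h - 1)] = np.nan
            # resample trace columns to original width (nearest column)
            src = np.clip(np.round(np.arange(w) * cw / w).astype(int), 0, cw - 1)
            out_traces[name] = t[src]
    return out_img, out_mask, out_traces
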