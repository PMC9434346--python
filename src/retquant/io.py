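"""File formats: grayscale PNG scans, indexed PNG masks, CSV traces/features."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import AnnotationSet, BScanImage, FEATURE_NAMES

# indexed-PNG palette: background, IRF, SRF, SHRM, PED
_PALETTE = [(0, 0, 0), (66, 135, 245), (52, 191, 163),
            (244, 180, 26), (214, 69, 65)]

FLOAT_FMT = "%.6g"


def write_image_png(path: str | Path, img: BScanImage | np.ndarray) -> None:
    data = img.intensity if isinstance(img, BScanImage) else np.asarray(img)
    arr = np.clip(np.round(data * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_image_png(path: str | Path,
                   pixel_size_mm: float = 8.0 / 1600.0) -> BScanImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0
    return BScanImage(arr, pixel_size_mm)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    im = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    palette = [v for rgb in _PALETTE for v in rgb]
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    im = Image.open(path)
    if im.mode != "P":
        im = im.convert("P")
    return np.asarray(im, dtype=np.uint8)


def write_traces_csv(path: str | Path, annotation: AnnotationSet) -> None:
    pd.DataFrame({
        "column": np.arange(annotation.ez_trace.size),
        "ez_row": annotation.ez_trace,
        "elm_row": annotation.elm_trace,
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_traces_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df["ez_row"].to_numpy(dtype=float),
            df["elm_row"].to_numpy(dtype=float))


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    cols = [c for c in ("eye_id", "visit") if c in table.columns]
    table = table[cols + [f for f in FEATURE_NAMES if f in table.columns]]
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
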