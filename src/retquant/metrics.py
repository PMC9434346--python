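"""Segmentation/detection metrics, bootstrap CIs and cohort accounting.

Dice and confusion metrics are computed by direct pixel/clip counting;
confidence intervals use the seeded percentile bootstrap; the AVG column of
the report is the arithmetic mean across biomarkers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPORT_BIOMARKERS = ("IRF", "SRF", "SHRM", "PED", "EZ", "ELM")
DICE_BIOMARKERS = ("IRF", "SRF", "SHRM", "PED")  # dice N/A for EZ/ELM


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); both-empty defined as 1 (perfect agreement)."""
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    denom = int(pred.sum()) + int(true.sum())
    if denom == 0:
        logger.debug("dice on two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int(np.logical_and(pred, true).sum()) / denom


def confusion_metrics(pred: np.ndarray, truth: np.ndarray
                      ) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN on undefined denominators."""
    pred = np.asarray(pred, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.size} vs {truth.size}")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty vectors")
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else math.nan
    specificity = tn / (tn + fp) if tn + fp else math.nan
    return accuracy, sensitivity, specificity


def bootstrap_ci(samples: np.ndarray, n_boot: int = 2000,
                 alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap over per-scan metric values."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty samples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, samples.size, size=(n_boot, samples.size))
    means = samples[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def aggregate_average(per_biomarker_values) -> float:
    """Arithmetic mean across biomarkers, reported to 3 decimals."""
    values = np.asarray(list(per_biomarker_values), dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    return round(float(values.mean()), 3)


def class_proportions(counts, decimals: int = 2) -> list[float]:
    """Per-category percentages 100 * count / total, rounded."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("counts must be non-empty with positive total")
    return [round(float(100.0 * c / counts.sum()), decimals) for c in counts]


def label_proportions(labels, decimals: int = 2) -> dict:
    """Per-class percentages from a list of class labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    counts = pd.Series(labels).value_counts().sort_index()
    pct = class_proportions(counts.to_numpy(), decimals=decimals)
    return dict(zip(counts.index.tolist(), pct))


@dataclass
class SegMetricsReport:
    """Per-biomarker metric table with CIs and the AVG aggregation."""

    table: pd.DataFrame   # rows: accuracy/sensitivity/specificity/dice
    ci_table: pd.DataFrame

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, float_format="%.3f", na_rep="N/A")


def evaluate_predictions(per_scan: dict[str, list[tuple[np.ndarray, np.ndarray]]],
                         n_boot: int = 1000, seed: int = 0
                         ) -> SegMetricsReport:
    """Build the report from per-biomarker lists of (pred, truth) pairs.

    Pixel-level pairs for the blocky lesion classes, clip-level pairs for
    EZ/ELM; dice is reported only for the blocky classes.
    """
    rows = {m: {} for m in ("accuracy", "sensitivity", "specificity", "dice")}
    cis = {m: {} for m in rows}
    for bio in REPORT_BIOMARKERS:
        pairs = per_scan.get(bio, [])
        if not pairs:
            for m in rows:
                rows[m][bio] = math.nan
            continue
        per_metric = {m: [] for m in rows}
        for pred, truth in pairs:
            acc, sen, spe = confusion_metrics(pred, truth)
            per_metric["accuracy"].append(acc)
            per_metric["sensitivity"].append(sen)
            per_metric["specificity"].append(spe)
            if bio in DICE_BIOMARKERS:
                per_metric["dice"].append(dice(pred, truth))
        for m, vals in per_metric.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[~np.isnan(arr)]
            if arr.size == 0:
                rows[m][bio] = math.nan
                continue
            rows[m][bio] = float(arr.mean())
            cis[m][bio] = bootstrap_ci(arr, n_boot=n_boot, seed=seed)
    table = pd.DataFrame(rows).T.reindex(columns=list(REPORT_BIOMARKERS))
    table["AVG"] = [aggregate_average(r.dropna()) if r.notna().any() else math.nan
                    for _n, r in table.iterrows()]
    ci_table = pd.DataFrame(cis).T.reindex(columns=list(REPORT_BIOMARKERS))
    return SegMetricsReport(table=table, ci_table=ci_table)
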