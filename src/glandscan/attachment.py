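"""Hemocyte-attachment quantification.

Hemocyte coverage of the gland surface is measured as a stained area and
summarized by the log-ratio statistic ``ln(hemocyte area) / ln(gland
area)``: the spatial distribution of attached hemocytes is roughly
log-like, so both areas are log-transformed before the ratio is formed.
Areas enter the statistic in **pixel** units, as in the original macro
workflow — the natural log is not scale-equivariant, so applying physical
calibration before the logs would change the statistic; this is deliberate
and recorded in the output metadata of the pipeline.

A hemocyte area of ≤ 1 px maps to statistic 0 ("no attachment"): ln of an
area ≤ 1 would be non-positive or undefined, and 0 is the natural floor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AttachmentMeasurement",
    "segment_marker_area",
    "attachment_statistic",
    "effect_size",
]


@dataclass
class AttachmentMeasurement:
    gland_id: str
    hemocyte_area_px: float
    gland_area_px2: float
    statistic: float
    compartment: str = "whole"  # whole | PP | DP
    timepoint: str = ""


def segment_marker_area(
    channel: np.ndarray,
    threshold: float,
    roi_mask: np.ndarray | None = None,
    median_filter: bool = False,
) -> int:
    """Count pixels above threshold (optionally median-filtered, 3×3),
    restricted to the gland ROI mask when given.

    The threshold is an explicit required parameter; a value outside the
    data range triggers a warning (the count is then 0 or the full area).
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("expected a single 2D channel")
    if threshold < channel.min() or threshold > channel.max():
        warnings.warn(
            f"threshold {threshold} outside data range "
            f"[{channel.min():g}, {channel.max():g}]",
            stacklevel=2,
        )
    if median_filter:
        channel = ndimage.median_filter(channel, size=3)
    fg = channel > threshold
    if roi_mask is not None:
        fg &= np.asarray(roi_mask, dtype=bool)
    return int(fg.sum())


def attachment_statistic(hemocyte_area_px: float, gland_area_px2: float) -> float:
    """ln(hemocyte area) / ln(gland area), with areas in pixels.

    Hemocyte area ≤ 1 px → 0 by convention; gland area < 2 px is an error
    (the denominator would be ≤ 0).
    """
    if gland_area_px2 < 2:
        raise ValueError("gland area must be at least 2 px (ln would be ≤ 0)")
    if hemocyte_area_px <= 1:
        return 0.0
    return math.log(hemocyte_area_px) / math.log(gland_area_px2)


def effect_size(
    effect_values: np.ndarray, reference_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize effect and reference samples by the reference mean.

    Anchors the reference mean at exactly 1, so effect values read as
    deviations from the reference (e.g. 0.33 = reduced to 33%).
    """
    effect = np.asarray(effect_values, dtype=float)
    reference = np.asarray(reference_values, dtype=float)
    ref_mean = reference.mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero; cannot normalize")
    return effect / ref_mean, reference / ref_mean
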