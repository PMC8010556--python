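"""Derived parameter maps and ROI summary statistics.

The quantities a reader records from a contoured lesion: the fat-fraction
map from a Dixon fat-only/water-only pair, the ADC map from a DWI stack via
an unweighted log-linear fit, and per-ROI mean / SD / area.

Invalid pixels (zero Dixon signal, non-positive DWI signal) are propagated
as NaN and excluded from ROI statistics rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, EmptyRoiError


@dataclass
class RoiStatistics:
    """Summary statistics of one ROI on one parameter map.

    ``n_pixels`` counts the valid (non-NaN) pixels that entered the mean
    and SD; ``n_masked`` counts all pixels under the mask. ``area_mm2`` is
    the valid-pixel count times the pixel area.
    """

    mean: float
    sd: float
    area_mm2: float
    n_pixels: int
    n_masked: int


def compute_ff_map(fo_map: np.ndarray, wo_map: np.ndarray) -> np.ndarray:
    """Fat-fraction map ``FF = FO / (FO + WO)`` as a fraction in [0, 1].

    Pixels where ``FO + WO == 0`` carry no Dixon signal and are returned as
    NaN (invalid), not zero.
    """
    fo = np.asarray(fo_map, dtype=float)
    wo = np.asarray(wo_map, dtype=float)
    if fo.shape != wo.shape:
        raise ConfigurationError(f"shape mismatch: FO {fo.shape} vs WO {wo.shape}")
    total = fo + wo
    ff = np.full(fo.shape, np.nan)
    valid = total > 0
    ff[valid] = fo[valid] / total[valid]
    return ff


def fit_adc_map(dwi_stack: np.ndarray, b_values: Sequence[float]) -> np.ndarray:
    """Per-pixel mono-exponential ADC from a DWI stack (mm^2/s).

    Ordinary least squares of ``ln S(b)`` on ``b`` over all b-values;
    ADC is the negated slope. Pixels with any non-positive signal are
    returned as NaN. Negative fitted ADCs are retained, not clamped.
    """
    b = np.asarray(b_values, dtype=float)
    stack = np.asarray(dwi_stack, dtype=float)
    if b.ndim != 1 or b.size < 2 or np.unique(b).size < 2:
        raise ConfigurationError("need at least two distinct b-values to fit ADC")
    if stack.shape[0] != b.size:
        raise ConfigurationError(
            f"dwi_stack leading dimension {stack.shape[0]} != number of b-values {b.size}"
        )
    invalid = (stack <= 0).any(axis=0)
    logs = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    b_c = b - b.mean()
    denom = (b_c**2).sum()
    bshape = (-1,) + (1,) * (stack.ndim - 1)
    slope = (b_c.reshape(bshape) * (logs - logs.mean(axis=0))).sum(axis=0) / denom
    adc = -slope
    adc[invalid] = np.nan
    return adc


def roi_statistics(
    image: np.ndarray, mask: np.ndarray, pixel_spacing=1.0, ddof: int = 1
) -> RoiStatistics:
    """Mean, SD and area of a map over a binary ROI mask.

    NaN pixels under the mask are excluded from the mean/SD and from the
    area, but counted in ``n_masked``. The SD denominator defaults to the
    sample convention (``ddof=1``); a single valid pixel yields SD 0.
    """
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if img.shape != msk.shape:
        raise ConfigurationError(f"shape mismatch: map {img.shape} vs mask {msk.shape}")
    if not msk.any():
        raise EmptyRoiError("ROI mask is empty")
    if np.isscalar(pixel_spacing):
        pixel_area = float(pixel_spacing) ** 2
    else:
        dy, dx = pixel_spacing
        pixel_area = float(dy) * float(dx)
    values = img[msk]
    valid = values[np.isfinite(values)]
    if valid.size == 0:
        raise EmptyRoiError("ROI contains no valid pixels")
    sd = float(np.std(valid, ddof=ddof)) if valid.size > ddof else 0.0
    return RoiStatistics(
        mean=float(valid.mean()),
        sd=sd,
        area_mm2=valid.size * pixel_area,
        n_pixels=int(valid.size),
        n_masked=int(msk.sum()),
    )


def roi_record(
    map_type: str,
    stats: RoiStatistics,
    subject_id: str,
    lesion_class: str,
    lesion_diameter_mm: float,
    reader: int,
    replicate: int,
) -> dict:
    """Format ROI statistics as one measurement-table row.

    FF maps are computed as fractions but tabulated in ml/100 ml, so their
    mean and SD are scaled by 100 here; ADC maps tabulate in 1e-6 mm^2/s.
    """
    if map_type == "FF":
        scale = 100.0
    elif map_type == "ADC":
        scale = 1e6
    else:
        raise ConfigurationError(f"unknown map type {map_type!r}")
    return {
        "subject_id": subject_id,
        "lesion_class": lesion_class,
        "lesion_diameter_mm": lesion_diameter_mm,
        "map": map_type,
        "reader": reader,
        "replicate": replicate,
        "roi_mean": stats.mean * scale,
        "roi_sd": stats.sd * scale,
        "roi_area_mm2": stats.area_mm2,
    }
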