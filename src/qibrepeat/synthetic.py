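"""Synthetic study data with known ground truth.

Two generators live here:

* :func:`generate_measurement_table` draws complete two-reader measurement
  tables (one small and one large lesion per subject, ADC and FF maps,
  three estimates per lesion: reader 1 twice, reader 2 once) with a known
  between-subject / intra-reader / inter-reader variance structure, so the
  downstream agreement analysis can be validated against configured truth.

* :func:`generate_lesion_phantom` rasterises a 2-D elliptical lesion into
  ADC and Dixon fat-only/water-only maps, and
  :func:`simulate_reader_contour` perturbs the true lesion boundary the way
  a human reader's manual ROI does (a smooth radial wobble plus a signed
  systematic erosion/dilation), so boundary-driven biases such as the
  small-lesion fat-fraction inflation can be reproduced mechanistically.

Measurement model
-----------------
For each subject x size class x map metric, a true lesion value is drawn
from ``Normal(true_group_mean, between_subject_sd)``. Reader 1's two
estimates add independent ``Normal(0, intra_reader_sw)`` noise, so the
intra-reader difference ``d = x11 - x12`` has variance ``2*intra_sw^2`` and
the within-subject SD ``sqrt(Var(d)/2)`` converges to ``intra_reader_sw``.
Reader 2's estimate adds ``Normal(0, s2)`` noise with
``s2 = sqrt(2*inter_sw^2 - intra_sw^2)``: the inter-reader difference then
has variance ``intra_sw^2 + s2^2 = 2*inter_sw^2``, so the measured
inter-reader within-subject SD converges to the configured
``inter_reader_sw`` — the configuration is stated in the units the analysis
estimates. This requires ``inter_sw >= intra_sw/sqrt(2)`` (enforced at
configuration time).

Every record derives its own random stream from the base seed and its
(subject, class, map, reader, replicate) coordinates, so tables are
reproducible record-wise and insensitive to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    LESION_CLASSES,
    MAP_TYPES,
    METRIC_COLUMNS,
    NONNEGATIVE_METRICS,
    POSITIVE_METRICS,
    StudyConfig,
)
from .exceptions import (
    ConfigurationError,
    DegenerateContourError,
    GeometryError,
)
from .quantmaps import compute_ff_map

_STATS = ("Mean", "SD", "Area")
_ESTIMATES = ((1, 1), (1, 2), (2, 1))  # (reader, replicate)

#: Exact column order of the measurement-table schema.
TABLE_COLUMNS = (
    "subject_id",
    "lesion_class",
    "lesion_diameter_mm",
    "map",
    "reader",
    "replicate",
    "roi_mean",
    "roi_sd",
    "roi_area_mm2",
)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Record-wise random stream: stable under generation order."""
    entropy = (int(seed) % (2**63),) + tuple(int(k) for k in key)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _draw_truth(rng: np.random.Generator, mean: float, sd: float, metric: str) -> float:
    """Per-lesion true value with the configured between-subject moments.

    Unbounded metrics (the map means) are Gaussian. Areas and pixel-SD
    metrics are positive, right-skewed quantities; their truth is drawn
    from a lognormal moment-matched to (mean, sd), which reproduces the
    configured between-subject mean and SD exactly without the variance
    shrinkage a truncated Gaussian would introduce when sd is a large
    fraction of the mean.
    """
    if sd == 0.0:
        return mean
    if metric in POSITIVE_METRICS or metric in NONNEGATIVE_METRICS:
        if mean <= 0:
            raise ConfigurationError(
                f"{metric}: true_group_mean must be > 0 when between_subject_sd > 0"
            )
        s2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - s2 / 2.0
        return math.exp(mu + math.sqrt(s2) * rng.standard_normal())
    return mean + sd * rng.standard_normal()


def _draw_constrained(rng: np.random.Generator, mean: float, sd: float, metric: str) -> float:
    """Normal draw, resampled until it satisfies the metric's support.

    Areas must be > 0 and SD metrics >= 0; plain truncated resampling keeps
    determinism (fixed stream, bounded retries) at the cost of a slight
    variance shrinkage when the support boundary is within a few SDs of the
    mean — negligible against the analysis' Monte Carlo tolerances.
    """
    if sd == 0.0:
        return mean
    for _ in range(10_000):
        value = mean + sd * rng.standard_normal()
        if metric in POSITIVE_METRICS and value <= 0.0:
            continue
        if metric in NONNEGATIVE_METRICS and value < 0.0:
            continue
        return value
    raise ConfigurationError(
        f"could not draw a valid value for {metric} with mean={mean}, sd={sd}"
    )


def generate_measurement_table(config: StudyConfig) -> pd.DataFrame:
    """Generate a complete synthetic measurement table.

    Returns a DataFrame with the exact measurement-table schema
    (:data:`TABLE_COLUMNS`): one row per subject x lesion class x map x
    estimate, i.e. ``12 * n_subjects`` rows. Deterministic given
    ``config.seed``; with all SDs zero every value equals its configured
    group mean.
    """
    config.validate()
    seed = config.seed
    rows = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:03d}"
        for c, lesion_class in enumerate(LESION_CLASSES):
            lo, hi = (
                config.small_diameter_mm if lesion_class == "small" else config.large_diameter_mm
            )
            diameter = float(_stream(seed, 2, s, c).uniform(lo, hi))
            for m, map_type in enumerate(MAP_TYPES):
                truth_rng = _stream(seed, 1, s, c, m)
                truths = {}
                for stat in _STATS:
                    metric = f"{map_type}-{stat}"
                    vc = config.components[(metric, lesion_class)]
                    truths[stat] = _draw_truth(
                        truth_rng, vc.true_group_mean, vc.between_subject_sd, metric
                    )
                for reader, replicate in _ESTIMATES:
                    est_rng = _stream(seed, 3, s, c, m, reader, replicate)
                    values = {}
                    for stat in _STATS:
                        metric = f"{map_type}-{stat}"
                        vc = config.components[(metric, lesion_class)]
                        if reader == 1:
                            noise_sd = vc.intra_reader_sw
                        else:
                            noise_sd = math.sqrt(
                                max(0.0, 2.0 * vc.inter_reader_sw**2 - vc.intra_reader_sw**2)
                            )
                        values[stat] = _draw_constrained(
                            est_rng, truths[stat], noise_sd, metric
                        )
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "lesion_class": lesion_class,
                            "lesion_diameter_mm": diameter,
                            "map": map_type,
                            "reader": reader,
                            "replicate": replicate,
                            "roi_mean": values["Mean"],
                            "roi_sd": values["SD"],
                            "roi_area_mm2": values["Area"],
                        }
                    )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


# ---------------------------------------------------------------------------
# 2-D lesion phantoms


@dataclass
class LesionSpec:
    """Contrast structure of one elliptical lesion on ADC and Dixon maps.

    ADC values are in mm^2/s (so 800e-6 is a typical active lesion);
    fat fractions are dimensionless in [0, 1]. ``dixon_total`` is the
    arbitrary FO+WO signal scale the Dixon pair is synthesised at.
    ``noise_sd`` maps ``{"adc", "fo", "wo"}`` to additive Gaussian noise SDs.
    """

    diameter_mm: float
    adc_lesion: float = 800e-6
    adc_background: float = 400e-6
    ff_lesion: float = 0.10
    ff_background: float = 0.60
    dixon_total: float = 100.0
    center_mm: Optional[Tuple[float, float]] = None
    eccentricity: float = 0.0
    noise_sd: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ConfigurationError(f"diameter_mm must be > 0, got {self.diameter_mm}")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ConfigurationError(f"eccentricity must be in [0, 1), got {self.eccentricity}")
        for name in ("ff_lesion", "ff_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.dixon_total <= 0:
            raise ConfigurationError(f"dixon_total must be > 0, got {self.dixon_total}")
        for k, v in self.noise_sd.items():
            if k not in ("adc", "fo", "wo"):
                raise ConfigurationError(f"noise_sd has unknown map key {k!r}")
            if v < 0:
                raise ConfigurationError(f"noise_sd[{k!r}] must be >= 0, got {v}")


@dataclass
class ContourSpec:
    """Model of a reader's manual ROI contour as a perturbed true boundary.

    The boundary is displaced radially (about the lesion centroid) by
    ``boundary_offset`` (mm; positive dilates, negative erodes) plus smooth
    zero-mean noise with pointwise SD ``radial_jitter_sd`` (mm),
    band-limited to ``angular_smoothness`` Fourier harmonics. Amplitudes
    are in millimetres, so small lesions suffer proportionally larger area
    errors — the mechanism behind size-dependent reader variability.
    """

    radial_jitter_sd: float = 0.5
    angular_smoothness: int = 4
    boundary_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radial_jitter_sd < 0:
            raise ConfigurationError(
                f"radial_jitter_sd must be >= 0, got {self.radial_jitter_sd}"
            )
        if self.angular_smoothness < 1:
            raise ConfigurationError(
                f"angular_smoothness must be >= 1, got {self.angular_smoothness}"
            )


@dataclass
class PhantomBundle:
    """A synthetic single-slice phantom: parameter maps plus ground truth."""

    adc_map: np.ndarray
    fo_map: np.ndarray
    wo_map: np.ndarray
    ff_map: np.ndarray
    true_mask: np.ndarray
    pixel_spacing: Tuple[float, float]
    lesion_spec: LesionSpec


def _as_spacing(pixel_spacing) -> Tuple[float, float]:
    if np.isscalar(pixel_spacing):
        return (float(pixel_spacing), float(pixel_spacing))
    dy, dx = pixel_spacing
    return (float(dy), float(dx))


def generate_lesion_phantom(
    spec: LesionSpec,
    pixel_spacing=1.0,
    shape: Tuple[int, int] = (64, 64),
    seed: int = 0,
) -> PhantomBundle:
    """Rasterise an elliptical lesion into ADC/FO/WO maps with noise.

    The ellipse's major axis (``spec.diameter_mm``) lies along x; the minor
    axis is shortened by the eccentricity. ``true_mask`` is the noise-free
    lesion support. FO and WO are synthesised as ``ff * total`` and
    ``(1-ff) * total``; after additive noise they are clipped at zero
    (magnitude images are non-negative) and the FF map is recomputed from
    the noisy pair, so ``ff_map = fo/(fo+wo)`` holds by construction.
    """
    dy, dx = _as_spacing(pixel_spacing)
    ny, nx = shape
    ys = np.arange(ny) * dy
    xs = np.arange(nx) * dx
    cy, cx = spec.center_mm if spec.center_mm is not None else ((ny - 1) * dy / 2, (nx - 1) * dx / 2)
    a = spec.diameter_mm / 2.0
    b = a * math.sqrt(1.0 - spec.eccentricity**2)
    if cx - a < 0 or cx + a > xs[-1] or cy - b < 0 or cy + b > ys[-1]:
        raise GeometryError(
            f"lesion (diameter {spec.diameter_mm} mm at ({cy}, {cx}) mm) does not fit in a "
            f"{ny}x{nx} grid at spacing ({dy}, {dx}) mm"
        )
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    true_mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    if not true_mask.any():
        raise GeometryError("rasterised lesion mask is empty; increase resolution")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed) % (2**63), 7)))
    noise = {k: spec.noise_sd.get(k, 0.0) for k in ("adc", "fo", "wo")}

    adc = np.where(true_mask, spec.adc_lesion, spec.adc_background).astype(float)
    ff_true = np.where(true_mask, spec.ff_lesion, spec.ff_background).astype(float)
    fo = ff_true * spec.dixon_total
    wo = (1.0 - ff_true) * spec.dixon_total
    if noise["adc"] > 0:
        adc = adc + noise["adc"] * rng.standard_normal(adc.shape)
    if noise["fo"] > 0:
        fo = fo + noise["fo"] * rng.standard_normal(fo.shape)
    if noise["wo"] > 0:
        wo = wo + noise["wo"] * rng.standard_normal(wo.shape)
    fo = np.clip(fo, 0.0, None)
    wo = np.clip(wo, 0.0, None)
    ff = compute_ff_map(fo, wo)
    return PhantomBundle(
        adc_map=adc,
        fo_map=fo,
        wo_map=wo,
        ff_map=ff,
        true_mask=true_mask,
        pixel_spacing=(dy, dx),
        lesion_spec=spec,
    )


def generate_dwi_from_adc(adc_map: np.ndarray, s0: float, b_values: Sequence[float]) -> np.ndarray:
    """Mono-exponential DWI stack ``S(b) = s0 * exp(-b * ADC)``.

    ``adc_map`` is in mm^2/s and ``b_values`` in s/mm^2; returns one grid
    per b-value, stacked along the first axis.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise ConfigurationError("b_values must be non-empty")
    if (b < 0).any():
        raise ConfigurationError(f"b_values must be non-negative, got {b_values}")
    adc = np.asarray(adc_map, dtype=float)
    if not np.isfinite(adc).all():
        raise ConfigurationError("adc_map must be finite")
    return s0 * np.exp(-b.reshape((-1,) + (1,) * adc.ndim) * adc[None, ...])


def simulate_reader_contour(
    true_mask: np.ndarray, contour: ContourSpec, pixel_spacing=1.0
) -> np.ndarray:
    """Perturb a lesion mask the way a manual reader contour does.

    A pixel belongs to the simulated ROI when its signed Euclidean distance
    to the true boundary (negative inside) does not exceed the radial
    displacement field ``offset + sum_k a_k cos(k*theta) + b_k sin(k*theta)``
    evaluated at the pixel's angle about the mask centroid. With zero
    jitter and zero offset the output equals ``true_mask`` exactly.
    Deterministic given ``contour.seed``.
    """
    mask = np.asarray(true_mask, dtype=bool)
    if not mask.any():
        raise DegenerateContourError("true_mask is empty")
    dy, dx = _as_spacing(pixel_spacing)
    area = mask.sum() * dy * dx
    radius = math.sqrt(area / math.pi)
    if abs(contour.boundary_offset) >= radius:
        raise DegenerateContourError(
            f"|boundary_offset|={abs(contour.boundary_offset)} mm is not smaller than the "
            f"effective lesion radius {radius:.3g} mm"
        )

    dist_in = ndimage.distance_transform_edt(mask, sampling=(dy, dx))
    dist_out = ndimage.distance_transform_edt(~mask, sampling=(dy, dx))
    # EDT measures pixel centre-to-centre; the true boundary runs half a
    # pixel beyond the innermost background centres, hence the 0.5h shift.
    h = (dy + dx) / 2.0
    sdf = np.where(mask, -(dist_in - 0.5 * h), dist_out - 0.5 * h)

    ny, nx = mask.shape
    Y, X = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
    cy = (Y * mask).sum() / mask.sum()
    cx = (X * mask).sum() / mask.sum()
    theta = np.arctan2(Y - cy, X - cx)

    displacement = np.full(mask.shape, contour.boundary_offset, dtype=float)
    if contour.radial_jitter_sd > 0:
        k_max = contour.angular_smoothness
        rng = np.random.default_rng(
            np.random.SeedSequence((int(contour.seed) % (2**63), 11))
        )
        amp = contour.radial_jitter_sd / math.sqrt(k_max)
        for k in range(1, k_max + 1):
            a_k, b_k = amp * rng.standard_normal(2)
            displacement += a_k * np.cos(k * theta) + b_k * np.sin(k * theta)

    out = sdf <= displacement
    if not out.any():
        raise DegenerateContourError("contour perturbation emptied the ROI")
    return out
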