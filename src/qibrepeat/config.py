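"""Study configuration for the synthetic measurement-table generator.

A two-reader lesion-measurement study is parameterised per *metric*
(ADC-Mean, ADC-SD, ADC-Area, FF-Mean, FF-SD, FF-Area) and per lesion size
class (small, large) by four variance components, all in the metric's own
units (ADC statistics in 1e-6 mm^2/s, FF statistics in ml/100 ml, areas in
mm^2):

``true_group_mean``
    population mean of the per-lesion true value,
``between_subject_sd``
    SD of the per-lesion true value across subjects,
``intra_reader_sw``
    within-subject SD targeted by the repeat measurements of one reader,
``inter_reader_sw``
    within-subject SD targeted by the comparison of two readers.

The configured ``*_sw`` values are what the downstream agreement analysis
should recover, not raw per-estimate noise SDs; see
:mod:`qibrepeat.synthetic` for how the per-estimate noise is calibrated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import yaml

from .exceptions import ConfigurationError

#: The six ROI summary metrics recorded per lesion, per map contrast.
METRICS: Tuple[str, ...] = (
    "ADC-Mean",
    "ADC-SD",
    "ADC-Area",
    "FF-Mean",
    "FF-SD",
    "FF-Area",
)

LESION_CLASSES: Tuple[str, ...] = ("small", "large")

MAP_TYPES: Tuple[str, ...] = ("ADC", "FF")

#: Metric name -> (map type, measurement-table column).
METRIC_COLUMNS: Dict[str, Tuple[str, str]] = {
    "ADC-Mean": ("ADC", "roi_mean"),
    "ADC-SD": ("ADC", "roi_sd"),
    "ADC-Area": ("ADC", "roi_area_mm2"),
    "FF-Mean": ("FF", "roi_mean"),
    "FF-SD": ("FF", "roi_sd"),
    "FF-Area": ("FF", "roi_area_mm2"),
}

#: Metrics whose values must be strictly positive (areas) or non-negative (SDs).
POSITIVE_METRICS = frozenset({"ADC-Area", "FF-Area"})
NONNEGATIVE_METRICS = frozenset({"ADC-SD", "FF-SD"})


@dataclass
class VarianceComponents:
    """Variance structure of one metric x lesion-class cell."""

    true_group_mean: float
    between_subject_sd: float
    intra_reader_sw: float
    inter_reader_sw: float

    def validate(self, label: str) -> None:
        for name in ("between_subject_sd", "intra_reader_sw", "inter_reader_sw"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{label}.{name} must be >= 0, got {getattr(self, name)}")
        # The reader-2 noise SD sqrt(2*inter^2 - intra^2) must be real: the
        # inter-reader difference variance can never fall below intra^2 because
        # reader 1's first estimate contributes its own noise to both comparisons.
        if self.inter_reader_sw < self.intra_reader_sw / math.sqrt(2.0) - 1e-12:
            raise ConfigurationError(
                f"{label}.inter_reader_sw={self.inter_reader_sw} is unattainable: "
                f"must be >= intra_reader_sw/sqrt(2) = {self.intra_reader_sw / math.sqrt(2.0):.6g}"
            )

    def to_dict(self) -> dict:
        return {
            "true_group_mean": self.true_group_mean,
            "between_subject_sd": self.between_subject_sd,
            "intra_reader_sw": self.intra_reader_sw,
            "inter_reader_sw": self.inter_reader_sw,
        }


@dataclass
class StudyConfig:
    """Full configuration of a synthetic two-reader repeatability study.

    Parameters
    ----------
    n_subjects
        Number of subjects; each contributes one small and one large lesion.
    components
        ``(metric, lesion_class) -> VarianceComponents`` for all 6 x 2 cells.
    small_diameter_mm, large_diameter_mm
        Inclusive diameter ranges the lesion diameters are drawn from
        (uniformly). The ranges must not overlap.
    seed
        Base seed; every record derives its own stream from it, so tables
        are reproducible record-wise.
    """

    n_subjects: int
    components: Dict[Tuple[str, str], VarianceComponents]
    small_diameter_mm: Tuple[float, float] = (5.0, 10.0)
    large_diameter_mm: Tuple[float, float] = (10.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for metric in METRICS:
            for cls in LESION_CLASSES:
                key = (metric, cls)
                if key not in self.components:
                    raise ConfigurationError(f"components missing cell {key}")
                self.components[key].validate(f"components[{metric},{cls}]")
        for name in ("small_diameter_mm", "large_diameter_mm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.small_diameter_mm[1] > self.large_diameter_mm[0]:
            raise ConfigurationError(
                "small_diameter_mm upper bound must not exceed large_diameter_mm lower bound"
            )
        if not isinstance(self.seed, int):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "small_diameter_mm": list(self.small_diameter_mm),
            "large_diameter_mm": list(self.large_diameter_mm),
            "components": {
                metric: {cls: self.components[(metric, cls)].to_dict() for cls in LESION_CLASSES}
                for metric in METRICS
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        try:
            components = {
                (metric, lcls): VarianceComponents(**vc)
                for metric, per_cls in d["components"].items()
                for lcls, vc in per_cls.items()
            }
            return cls(
                n_subjects=int(d["n_subjects"]),
                components=components,
                small_diameter_mm=tuple(d.get("small_diameter_mm", (5.0, 10.0))),
                large_diameter_mm=tuple(d.get("large_diameter_mm", (10.0, 30.0))),
                seed=int(d["seed"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing configuration field {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable SHA-256 digest of the canonical configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def with_overrides(self, **kwargs) -> "StudyConfig":
        d = self.to_dict()
        d.update(kwargs)
        return StudyConfig.from_dict(d)
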