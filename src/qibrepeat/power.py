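"""Monte Carlo power and sample size for Levene's test of an SD ratio.

The study-design question: how many lesions per size group are needed so
that Levene's test (two-sided, alpha = 0.05) detects a within-subject SD
ratio of 2 between the small- and large-lesion difference distributions
with 80% power? Per replicate, one group of per-subject differences is
drawn from ``Normal(0, 1)`` and the other from ``Normal(0, sd_ratio)``
(the scale is irrelevant to the test), Levene's W is computed, and power
is the rejection fraction over many replicates. Group pairing is ignored,
matching how Levene's independent-groups test is applied to the real data.

The two-group Levene statistic is evaluated vectorised over replicates, so
100,000-replicate runs take seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError

_CHUNK = 20_000  # replicates per vectorised block; bounds memory


@dataclass
class PowerEstimate:
    """Monte Carlo power of Levene's test at one design point."""

    n_per_group: int
    sd_ratio: float
    alpha: float
    n_sim: int
    power: float
    mc_se: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "sd_ratio": self.sd_ratio,
            "alpha": self.alpha,
            "n_sim": self.n_sim,
            "power": self.power,
            "mc_se": self.mc_se,
            "seed": self.seed,
        }


@dataclass
class SampleSizeResult:
    """Smallest group size reaching a target power, with the power curve."""

    target_power: float
    n_required: Optional[int]
    achieved: bool
    curve: List[PowerEstimate]

    def to_dict(self) -> dict:
        return {
            "target_power": self.target_power,
            "n_required": self.n_required,
            "achieved": self.achieved,
            "curve": [p.to_dict() for p in self.curve],
        }


def _levene_w_2group(x: np.ndarray, y: np.ndarray, center: str) -> np.ndarray:
    """Vectorised two-group Levene W: one statistic per row of x/y."""
    if center == "mean":
        zx = np.abs(x - x.mean(axis=1, keepdims=True))
        zy = np.abs(y - y.mean(axis=1, keepdims=True))
    else:
        zx = np.abs(x - np.median(x, axis=1, keepdims=True))
        zy = np.abs(y - np.median(y, axis=1, keepdims=True))
    n1, n2 = x.shape[1], y.shape[1]
    n_total = n1 + n2
    mx = zx.mean(axis=1)
    my = zy.mean(axis=1)
    grand = (n1 * mx + n2 * my) / n_total
    ssb = n1 * (mx - grand) ** 2 + n2 * (my - grand) ** 2
    ssw = ((zx - mx[:, None]) ** 2).sum(axis=1) + ((zy - my[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (n_total - 2) * ssb / ssw


def simulate_power(
    n_per_group: int,
    sd_ratio: float,
    alpha: float = 0.05,
    n_sim: int = 100_000,
    seed: int = 0,
    center: str = "mean",
    distribution: str = "normal",
) -> PowerEstimate:
    """Monte Carlo power of Levene's test for a given SD ratio.

    Per replicate, draws ``n_per_group`` differences from a zero-mean
    distribution with SD 1 and ``n_per_group`` with SD ``sd_ratio``, and
    rejects when Levene's W exceeds the ``F(1, 2n-2)`` critical value at
    ``alpha``. ``distribution='laplace'`` substitutes a heavier-tailed
    model for sensitivity analysis. Deterministic given ``seed``.
    """
    if n_per_group < 3:
        raise ConfigurationError(f"n_per_group must be >= 3, got {n_per_group}")
    if sd_ratio < 1.0:
        raise ConfigurationError(f"sd_ratio must be >= 1, got {sd_ratio}")
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n_sim < 100:
        raise ConfigurationError(f"n_sim must be >= 100, got {n_sim}")
    if distribution not in ("normal", "laplace"):
        raise ConfigurationError(f"distribution must be 'normal' or 'laplace', got {distribution!r}")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed) % (2**63), 17)))
    crit = stats.f.ppf(1.0 - alpha, 1, 2 * n_per_group - 2)
    rejections = 0
    done = 0
    while done < n_sim:
        m = min(_CHUNK, n_sim - done)
        if distribution == "normal":
            x = rng.standard_normal((m, n_per_group))
            y = sd_ratio * rng.standard_normal((m, n_per_group))
        else:
            # unit-SD Laplace has scale 1/sqrt(2)
            x = rng.laplace(scale=1.0 / math.sqrt(2.0), size=(m, n_per_group))
            y = rng.laplace(scale=sd_ratio / math.sqrt(2.0), size=(m, n_per_group))
        w = _levene_w_2group(x, y, center)
        rejections += int(np.count_nonzero(w > crit))
        done += m
    power = rejections / n_sim
    return PowerEstimate(
        n_per_group=n_per_group,
        sd_ratio=sd_ratio,
        alpha=alpha,
        n_sim=n_sim,
        power=power,
        mc_se=math.sqrt(power * (1.0 - power) / n_sim),
        seed=seed,
    )


def required_sample_size(
    target_power: float,
    sd_ratio: float,
    alpha: float = 0.05,
    n_sim: int = 100_000,
    n_range: Tuple[int, int] = (3, 60),
    seed: int = 0,
    center: str = "mean",
) -> SampleSizeResult:
    """Smallest per-group n whose simulated power reaches ``target_power``.

    Scans ``n_range`` (inclusive) with a per-n derived seed, returning the
    smallest n whose estimated power is at least the target together with
    the full power curve. If no n in the range reaches the target the
    result carries ``achieved=False`` and the curve.
    """
    if not (0.0 < target_power < 1.0):
        raise ConfigurationError(f"target_power must be in (0, 1), got {target_power}")
    n_min, n_max = n_range
    if n_min > n_max or n_min < 3:
        raise ConfigurationError(f"invalid n_range {n_range}; need 3 <= n_min <= n_max")
    curve: List[PowerEstimate] = []
    n_required: Optional[int] = None
    for n in range(n_min, n_max + 1):
        sub_seed = int(np.random.SeedSequence((int(seed) % (2**63), 23, n)).generate_state(1)[0] % (2**31))
        est = simulate_power(
            n, sd_ratio, alpha=alpha, n_sim=n_sim, seed=sub_seed, center=center
        )
        curve.append(est)
        if n_required is None and est.power >= target_power:
            n_required = n
    return SampleSizeResult(
        target_power=target_power,
        n_required=n_required,
        achieved=n_required is not None,
        curve=curve,
    )
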