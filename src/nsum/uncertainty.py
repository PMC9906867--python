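"""Monte Carlo and bootstrap uncertainty intervals for the scale-up estimate.

Two complementary constructions:

* **Monte Carlo** — parametric: the total alter count ``sum m`` and the
  total network size ``sum c`` are redrawn as Poisson variates with means
  equal to their observed values, and (optionally) the visibility and
  popularity factors are redrawn uniformly over their stated ranges.  Each
  replicate recomputes ``e* = (sum m* / sum c*) * t * VF* * PF*`` and the
  interval is a percentile band of the replicates.
* **Bootstrap** — nonparametric: respondents are resampled with
  replacement (gender-stratified by default, since degrees are
  gender-specific) and the adjusted estimate recomputed with the point
  factors.

Per-respondent Poisson draws with means ``c_male``/``c_female`` sum to a
single Poisson draw with the aggregate mean, so the Monte Carlo uses one
aggregate draw per replicate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import NetworkConfig
from .survey import Gender, SurveyRespondent

__all__ = ["IntervalMethod", "UncertaintyResult", "monte_carlo_interval", "bootstrap_interval"]

_BOOT_CHUNK = 1000  # replicates per multinomial block; bounds peak memory


class IntervalMethod(str, enum.Enum):
    MONTE_CARLO = "monte_carlo"
    BOOTSTRAP = "bootstrap"


@dataclass(frozen=True)
class UncertaintyResult:
    """Percentile uncertainty interval from replicate estimates.

    ``lower``/``upper`` are the ``level_low``/``level_high`` percentiles of
    the replicate distribution; ``point`` is the deterministic adjusted
    estimate the replicates scatter around.  ``draws`` holds the replicate
    estimates when requested at construction.
    """

    method: IntervalMethod
    point: float
    lower: float
    upper: float
    level_low: float
    level_high: float
    n_replicates: int
    seed: int | None
    draws: np.ndarray | None = None
    #: Monte Carlo only: the replicate numerator totals (sum m*), kept with
    #: ``draws`` so the Poisson replicate distribution itself is inspectable
    m_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval endpoints out of order")

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "level_low": self.level_low,
            "level_high": self.level_high,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }


def _check_common(n_replicates: int, percentiles: tuple[float, float]) -> None:
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    lo, hi = percentiles
    if not (0 <= lo < hi <= 100):
        raise ValueError("percentiles must be an ordered pair within [0, 100]")


def _aggregates(
    respondents: Sequence[SurveyRespondent], config: NetworkConfig
) -> tuple[int, float, float]:
    n_male = sum(1 for r in respondents if r.gender is Gender.MALE)
    n_female = len(respondents) - n_male
    sum_m = sum(r.m for r in respondents)
    sum_c = n_male * config.c_male + n_female * config.c_female
    return sum_m, sum_c, n_male * config.c_male


def monte_carlo_interval(
    respondents: Sequence[SurveyRespondent],
    config: NetworkConfig,
    n_replicates: int = 10_000,
    percentiles: tuple[float, float] = (2.5, 97.5),
    sample_factors: bool = True,
    seed: int | None = None,
    keep_draws: bool = False,
) -> UncertaintyResult:
    """Parametric Monte Carlo interval around the adjusted estimate.

    Per replicate: ``sum m* ~ Poisson(sum m)``, ``sum c* ~ Poisson(sum c)``
    (zero-truncated; a zero network total carries no information) and, when
    ``sample_factors``, ``VF* ~ U(vf_range)`` and ``PF* ~ U(pf_range)``,
    otherwise the point factors.  Reproducible for a fixed ``seed``.
    """
    _check_common(n_replicates, percentiles)
    if not respondents:
        raise ValueError("at least one respondent is required")
    sum_m, sum_c, _ = _aggregates(respondents, config)
    rng = np.random.default_rng(seed)

    m_star = rng.poisson(sum_m, size=n_replicates).astype(float)
    c_star = rng.poisson(sum_c, size=n_replicates).astype(float)
    zero = c_star == 0
    while zero.any():  # vanishingly rare at realistic sum_c
        c_star[zero] = rng.poisson(sum_c, size=int(zero.sum()))
        zero = c_star == 0
    if sample_factors:
        vf = rng.uniform(*config.vf_range, size=n_replicates)
        pf = rng.uniform(*config.pf_range, size=n_replicates)
    else:
        vf = config.vf_point
        pf = config.pf_point
    draws = m_star / c_star * config.t * vf * pf

    lower, upper = np.percentile(draws, percentiles)
    point = sum_m / sum_c * config.t * config.vf_point * config.pf_point
    return UncertaintyResult(
        method=IntervalMethod.MONTE_CARLO,
        point=point, lower=float(lower), upper=float(upper),
        level_low=percentiles[0], level_high=percentiles[1],
        n_replicates=n_replicates, seed=seed,
        draws=draws if keep_draws else None,
        m_draws=m_star if keep_draws else None,
    )


def bootstrap_interval(
    respondents: Sequence[SurveyRespondent],
    config: NetworkConfig,
    n_replicates: int = 10_000,
    percentiles: tuple[float, float] = (2.5, 97.5),
    stratified: bool = True,
    seed: int | None = None,
    keep_draws: bool = False,
) -> UncertaintyResult:
    """Percentile bootstrap interval from resampling respondents.

    With ``stratified`` (default) resampling is within gender, preserving
    the male/female split and hence the network-size denominator; without
    it respondents are resampled from the pooled survey and the denominator
    varies with the resampled gender mix.

    Resampling ``n`` respondents with replacement is realised as a
    multinomial count vector over the ``n`` originals, so the replicate sum
    is a dot product — no index matrices are materialised.
    """
    _check_common(n_replicates, percentiles)
    if len(respondents) < 2:
        raise ValueError("bootstrap requires at least 2 respondents")
    rng = np.random.default_rng(seed)

    m = np.array([r.m for r in respondents], dtype=float)
    c = np.array([config.degree(r.gender) for r in respondents], dtype=float)
    male = np.array([r.gender is Gender.MALE for r in respondents])

    draws = np.empty(n_replicates, dtype=float)
    for start in range(0, n_replicates, _BOOT_CHUNK):
        stop = min(start + _BOOT_CHUNK, n_replicates)
        k = stop - start
        if stratified:
            sum_m = np.zeros(k)
            sum_c = 0.0
            for mask in (male, ~male):
                n_g = int(mask.sum())
                if n_g == 0:
                    continue
                counts = rng.multinomial(n_g, np.full(n_g, 1.0 / n_g), size=k)
                sum_m += counts @ m[mask]
                sum_c += n_g * c[mask][0]
            draws[start:stop] = sum_m / sum_c * config.t
        else:
            n = len(respondents)
            counts = rng.multinomial(n, np.full(n, 1.0 / n), size=k)
            draws[start:stop] = (counts @ m) / (counts @ c) * config.t
    draws *= config.vf_point * config.pf_point

    lower, upper = np.percentile(draws, percentiles)
    sum_m_obs, sum_c_obs, _ = _aggregates(respondents, config)
    point = sum_m_obs / sum_c_obs * config.t * config.vf_point * config.pf_point
    return UncertaintyResult(
        method=IntervalMethod.BOOTSTRAP,
        point=point, lower=float(lower), upper=float(upper),
        level_low=percentiles[0], level_high=percentiles[1],
        n_replicates=n_replicates, seed=seed,
        draws=draws if keep_draws else None,
    )
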