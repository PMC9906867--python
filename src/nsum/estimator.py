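"""The network scale-up point estimator and its correction-factor adjustments.

The core statistic is the scale-up ratio

    e = (sum_i m_i / sum_i c_i) * t

where ``m_i`` is the number of hidden-population alters respondent *i*
reports, ``c_i`` their personal network size (degree) and ``t`` the
reference population total.  The crude estimate is then multiplied by the
visibility factor (VF) and the popularity factor (PF) to correct,
respectively, for the transparency barrier (respondents do not know every
alter's hidden status) and the barrier effect (hidden-population members
have smaller networks than average):

    e_adjusted = e * VF * PF

The model/results pair follows the statsmodels idiom: build a
:class:`NetworkScaleUp` model from respondent data and a
:class:`~nsum.config.NetworkConfig`, call :meth:`~NetworkScaleUp.fit`, and
work with the returned :class:`NsumResults` (intervals, sensitivity scans,
``summary()``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import pandas as pd
from scipy import stats

from .config import NetworkConfig
from .survey import Gender, SurveyRespondent, respondents_from_dataframe

if TYPE_CHECKING:  # pragma: no cover
    from .sensitivity import SensitivityRow
    from .uncertainty import UncertaintyResult

__all__ = [
    "NsumEstimate",
    "crude_estimate",
    "apply_adjustments",
    "prevalence",
    "required_sample_size",
    "NetworkScaleUp",
    "NsumResults",
]


@dataclass(frozen=True)
class NsumEstimate:
    """Scale-up estimate with the provenance of each adjustment.

    ``e_vf``/``e_pf``/``e_adjusted``/``prevalence_per_1000`` are ``None``
    until :func:`apply_adjustments` has been applied.  All values are kept
    at full precision; rounding happens only at report time.
    """

    sum_m: int
    sum_c: float
    t: int
    e_crude: float
    e_vf: float | None = None
    e_pf: float | None = None
    e_adjusted: float | None = None
    prevalence_per_1000: float | None = None
    zero_reports: bool = False

    @property
    def adjusted(self) -> bool:
        return self.e_adjusted is not None


def crude_estimate(
    respondents: Sequence[SurveyRespondent], config: NetworkConfig
) -> NsumEstimate:
    """Crude scale-up estimate ``(sum m / sum c) * t`` from a survey.

    The denominator uses the fixed per-gender degrees from ``config``:
    ``sum_c = n_male * c_male + n_female * c_female``.

    A survey with no reported alters at all yields estimate 0 with the
    ``zero_reports`` flag set (and a warning), not an error.
    """
    if not respondents:
        raise ValueError("at least one respondent is required")
    n_male = sum(1 for r in respondents if r.gender is Gender.MALE)
    n_female = len(respondents) - n_male
    sum_m = sum(r.m for r in respondents)
    sum_c = n_male * config.c_male + n_female * config.c_female
    if sum_c <= 0:
        raise ValueError("total personal network size must be positive")
    zero = sum_m == 0
    if zero:
        warnings.warn("no hidden-population alters reported; estimate is 0", stacklevel=2)
    return NsumEstimate(
        sum_m=sum_m, sum_c=sum_c, t=config.t,
        e_crude=sum_m / sum_c * config.t, zero_reports=zero,
    )


def apply_adjustments(estimate: NsumEstimate, config: NetworkConfig) -> NsumEstimate:
    """Multiply the crude estimate by the visibility and popularity factors.

    The factors are pure multipliers, so the order is immaterial; the
    singly-adjusted values ``e_vf`` and ``e_pf`` are kept for table-style
    reporting.
    """
    if config.vf_point <= 0 or config.pf_point <= 0:
        raise ValueError("correction factors must be strictly positive")
    e_adj = estimate.e_crude * config.vf_point * config.pf_point
    return replace(
        estimate,
        e_vf=estimate.e_crude * config.vf_point,
        e_pf=estimate.e_crude * config.pf_point,
        e_adjusted=e_adj,
        prevalence_per_1000=e_adj / estimate.t * 1000,
    )


def prevalence(estimate: NsumEstimate, config: NetworkConfig, per: int = 1000) -> float:
    """Adjusted estimate as a rate per ``per`` members of the reference population."""
    if per <= 0:
        raise ValueError("per must be a positive integer")
    if estimate.e_adjusted is None:
        raise ValueError("apply_adjustments before converting to prevalence")
    return estimate.e_adjusted / config.t * per


def required_sample_size(
    p: float,
    d: float,
    confidence: float = 0.95,
    nonresponse: float = 0.0,
    inflation: str = "multiply",
) -> int:
    """Survey sample size for estimating a proportion to absolute error ``d``.

    Computes ``n0 = z^2 p (1-p) / d^2`` with ``z`` the standard-normal
    quantile at ``(1+confidence)/2``, then inflates for nonresponse either
    by multiplying by ``1 + nonresponse`` (default; the common field
    convention) or by dividing by ``1 - nonresponse``; the result is
    rounded up.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if not 0 <= nonresponse < 1:
        raise ValueError("nonresponse must be in [0, 1)")
    if inflation not in ("multiply", "divide"):
        raise ValueError("inflation must be 'multiply' or 'divide'")
    z = stats.norm.ppf((1 + confidence) / 2)
    n0 = z**2 * p * (1 - p) / d**2
    n = n0 * (1 + nonresponse) if inflation == "multiply" else n0 / (1 - nonresponse)
    return math.ceil(n)


class NetworkScaleUp:
    """Network scale-up model for a respondent-level survey.

    Parameters
    ----------
    respondents : sequence of SurveyRespondent
        The survey; only gender and the alter count ``m`` enter the
        estimator, but full records enable bootstrap resampling and
        demographic tables.
    config : NetworkConfig
        Degrees, reference population and correction factors.

    Examples
    --------
    >>> model = NetworkScaleUp.from_counts(495, 505, 434, NetworkConfig())
    >>> res = model.fit()
    >>> round(res.e_adjusted)
    4847
    """

    def __init__(
        self, respondents: Sequence[SurveyRespondent], config: NetworkConfig
    ) -> None:
        if not respondents:
            raise ValueError("at least one respondent is required")
        self.respondents = list(respondents)
        self.config = config

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: NetworkConfig,
        schema: Mapping[str, str] | None = None,
    ) -> "NetworkScaleUp":
        """Build the model from a respondent DataFrame (validated on entry)."""
        return cls(respondents_from_dataframe(df, schema=schema), config)

    @classmethod
    def from_counts(
        cls,
        n_male: int,
        n_female: int,
        sum_m: int,
        config: NetworkConfig,
        seed: int | None = None,
    ) -> "NetworkScaleUp":
        """Build the model from published aggregates instead of raw records.

        Reconstructs a minimal respondent list with the given gender split
        and total alter count by spreading the ``sum_m`` reports one at a
        time over the respondents (in seeded-random order when ``seed`` is
        given, round-robin otherwise).  The scale-up point estimate depends
        only on these aggregates, so any such allocation reproduces it
        exactly; resampling-based intervals, however, do depend on how the
        reports are spread.
        """
        import numpy as np

        n = n_male + n_female
        if n <= 0 or min(n_male, n_female) < 0 or sum_m < 0:
            raise ValueError("counts must be non-negative with at least one respondent")
        counts = [0] * n
        order = list(range(n))
        if seed is not None:
            rng = np.random.default_rng(seed)
        for k in range(sum_m):
            if k % n == 0 and seed is not None:
                rng.shuffle(order)
            counts[order[k % n]] += 1
        respondents = [
            SurveyRespondent(
                id=f"r{i + 1:04d}",
                gender=Gender.MALE if i < n_male else Gender.FEMALE,
                m=counts[i],
            )
            for i in range(n)
        ]
        return cls(respondents, config)

    @property
    def n_male(self) -> int:
        return sum(1 for r in self.respondents if r.gender is Gender.MALE)

    @property
    def n_female(self) -> int:
        return len(self.respondents) - self.n_male

    def fit(self) -> "NsumResults":
        """Compute the crude and factor-adjusted estimates."""
        est = apply_adjustments(crude_estimate(self.respondents, self.config), self.config)
        return NsumResults(self, est)


class NsumResults:
    """Fitted scale-up estimates with uncertainty and sensitivity methods.

    Exposes the chain of estimates (``e_crude``, ``e_vf``, ``e_pf``,
    ``e_adjusted``, ``prevalence_per_1000``) as attributes and hangs the
    Monte Carlo / bootstrap interval constructions and the degree
    sensitivity scan off the fitted object.
    """

    def __init__(self, model: NetworkScaleUp, estimate: NsumEstimate) -> None:
        self.model = model
        self.estimate = estimate

    # -- delegated scalar results ------------------------------------
    @property
    def sum_m(self) -> int:
        return self.estimate.sum_m

    @property
    def sum_c(self) -> float:
        return self.estimate.sum_c

    @property
    def e_crude(self) -> float:
        return self.estimate.e_crude

    @property
    def e_vf(self) -> float:
        return self.estimate.e_vf

    @property
    def e_pf(self) -> float:
        return self.estimate.e_pf

    @property
    def e_adjusted(self) -> float:
        return self.estimate.e_adjusted

    @property
    def prevalence_per_1000(self) -> float:
        return self.estimate.prevalence_per_1000

    def prevalence(self, per: int = 1000) -> float:
        """Adjusted estimate per ``per`` of the reference population."""
        return prevalence(self.estimate, self.model.config, per=per)

    # -- uncertainty and sensitivity ---------------------------------
    def monte_carlo_interval(
        self,
        n_replicates: int = 10_000,
        percentiles: tuple[float, float] = (2.5, 97.5),
        sample_factors: bool = True,
        seed: int | None = None,
        keep_draws: bool = False,
    ) -> "UncertaintyResult":
        from .uncertainty import monte_carlo_interval

        return monte_carlo_interval(
            self.model.respondents, self.model.config,
            n_replicates=n_replicates, percentiles=percentiles,
            sample_factors=sample_factors, seed=seed, keep_draws=keep_draws,
        )

    def bootstrap_interval(
        self,
        n_replicates: int = 10_000,
        percentiles: tuple[float, float] = (2.5, 97.5),
        stratified: bool = True,
        seed: int | None = None,
        keep_draws: bool = False,
    ) -> "UncertaintyResult":
        from .uncertainty import bootstrap_interval

        return bootstrap_interval(
            self.model.respondents, self.model.config,
            n_replicates=n_replicates, percentiles=percentiles,
            stratified=stratified, seed=seed, keep_draws=keep_draws,
        )

    def sensitivity_scan(self, scales: Sequence[float]) -> "list[SensitivityRow]":
        from .sensitivity import sensitivity_scan

        return sensitivity_scan(self.model.respondents, self.model.config, scales)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the estimate chain."""
        cfg = self.model.config
        lines = [
            "Network scale-up estimate",
            "=" * 58,
            f"Respondents            {len(self.model.respondents):>10d}"
            f"   (male {self.model.n_male}, female {self.model.n_female})",
            f"Reported alters (sum m){self.sum_m:>10d}",
            f"Network total (sum c)  {self.sum_c:>10.0f}",
            f"Reference population t {cfg.t:>10d}",
            "-" * 58,
            f"Crude estimate         {self.e_crude:>10.1f}",
            f"Visibility-adjusted    {self.e_vf:>10.1f}   (VF = {cfg.vf_point:.4f})",
            f"Popularity-adjusted    {self.e_pf:>10.1f}   (PF = {cfg.pf_point:.4f})",
            f"Fully adjusted         {self.e_adjusted:>10.1f}",
            f"Prevalence per 1000    {self.prevalence_per_1000:>10.2f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Estimate chain as a JSON-serialisable mapping (full precision)."""
        return {
            "n_respondents": len(self.model.respondents),
            "n_male": self.model.n_male,
            "n_female": self.model.n_female,
            "sum_m": self.sum_m,
            "sum_c": self.sum_c,
            "t": self.model.config.t,
            "e_crude": self.e_crude,
            "e_vf": self.e_vf,
            "e_pf": self.e_pf,
            "e_adjusted": self.e_adjusted,
            "prevalence_per_1000": self.prevalence_per_1000,
            "zero_reports": self.estimate.zero_reports,
        }
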