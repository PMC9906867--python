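"""Sensitivity of the adjusted estimate to the assumed personal network sizes.

The degrees (90 for men, 120 for women) are borrowed from another city's
study, so the estimate is recomputed under scaled degrees.  Because the
degrees enter only through the denominator, the adjusted estimate obeys an
exact reciprocal law: scaling every degree by ``s`` divides the estimate by
``s``.  The scan recomputes each row from scratch rather than applying the
law, so the law doubles as an internal consistency check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .config import NetworkConfig
from .estimator import apply_adjustments, crude_estimate
from .survey import SurveyRespondent

__all__ = ["SensitivityRow", "sensitivity_scan"]


@dataclass(frozen=True)
class SensitivityRow:
    """Adjusted estimate under degrees scaled by ``scale``."""

    scale: float
    e_adjusted: float
    prevalence_per_1000: float


def sensitivity_scan(
    respondents: Sequence[SurveyRespondent],
    config: NetworkConfig,
    scales: Sequence[float],
    scale_male: bool = True,
    scale_female: bool = True,
) -> list[SensitivityRow]:
    """Recompute the fully adjusted estimate for each degree scale factor.

    By default both genders' degrees are scaled together (the borrowed
    network size is questioned wholesale); ``scale_male``/``scale_female``
    restrict the scaling to one gender for finer-grained scans.  Rows come
    back in the order the scales were given.
    """
    if not scales:
        raise ValueError("at least one scale is required")
    for s in scales:
        if s <= 0:
            raise ValueError(f"scales must be strictly positive, got {s}")
    if not (scale_male or scale_female):
        raise ValueError("at least one gender's degrees must be scaled")
    rows = []
    for s in scales:
        scaled = NetworkConfig(
            c_male=config.c_male * (s if scale_male else 1.0),
            c_female=config.c_female * (s if scale_female else 1.0),
            t=config.t,
            vf_point=config.vf_point, vf_range=config.vf_range,
            pf_point=config.pf_point, pf_range=config.pf_range,
            percent_denominator=config.percent_denominator,
        )
        est = apply_adjustments(crude_estimate(respondents, scaled), scaled)
        rows.append(
            SensitivityRow(
                scale=float(s),
                e_adjusted=est.e_adjusted,
                prevalence_per_1000=est.prevalence_per_1000,
            )
        )
    return rows
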