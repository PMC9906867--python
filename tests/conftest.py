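"""Shared fixtures: the study-scale survey aggregates and record builders."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from nsum import NetworkConfig, NetworkScaleUp
from nsum.survey import (
    AgeGroup,
    AlterMaritalStatus,
    AlterRecord,
    Education,
    Gender,
    MaritalStatus,
    NChildren,
    SurveyRespondent,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_config() -> NetworkConfig:
    """Degrees 90/120, t = 406,916, VF = 1/0.45, PF = 1/0.77."""
    return NetworkConfig()


@pytest.fixture(scope="session")
def study_model(study_config: NetworkConfig) -> NetworkScaleUp:
    """1000 respondents (495 male, 505 female) reporting 434 alters in total."""
    return NetworkScaleUp.from_counts(495, 505, 434, study_config, seed=0)


@pytest.fixture(scope="session")
def study_results(study_model: NetworkScaleUp):
    return study_model.fit()


def respondents_strategy(min_size: int = 1, max_size: int = 30, max_m: int = 20):
    """Hypothesis strategy over small, fully-populated respondent lists."""

    def build(values: list[tuple]) -> list[SurveyRespondent]:
        return [
            SurveyRespondent(
                id=f"r{i:03d}", gender=g, m=m,
                age_group=a, education=e, marital_status=ms,
            )
            for i, (g, m, a, e, ms) in enumerate(values)
        ]

    row = st.tuples(
        st.sampled_from(Gender),
        st.integers(min_value=0, max_value=max_m),
        st.one_of(st.none(), st.sampled_from(AgeGroup)),
        st.one_of(st.none(), st.sampled_from(Education)),
        st.one_of(st.none(), st.sampled_from(MaritalStatus)),
    )
    return st.lists(row, min_size=min_size, max_size=max_size).map(build)


def make_alter_table() -> list[AlterRecord]:
    """434 alter records whose per-variable marginals equal the study's
    published FSW-alter frequency table (each variable filled independently)."""
    def expand(pairs):
        out = []
        for cat, n in pairs:
            out.extend([cat] * n)
        return out

    ages = expand([(AgeGroup.A18_29, 259), (AgeGroup.A30_44, 155), (AgeGroup.A45_65, 20)])
    edus = expand(
        [(Education.ILLITERATE, 11), (Education.ELEMENTARY, 46),
         (Education.GUIDANCE, 206), (Education.DIPLOMA_PLUS, 171)]
    )
    mars = expand(
        [(AlterMaritalStatus.SINGLE, 145), (AlterMaritalStatus.MARRIED, 121),
         (AlterMaritalStatus.DIVORCED, 132), (AlterMaritalStatus.WIDOW, 36)]
    )
    kids = expand(
        [(NChildren.NONE, 243), (NChildren.ONE, 101), (NChildren.TWO, 71),
         (NChildren.THREE_PLUS, 19)]
    )
    alcohol = expand([(True, 126), (False, 308)])
    prison = expand([(True, 22), (False, 412)])
    drug = expand([(True, 64), (False, 370)])
    return [
        AlterRecord(
            respondent_id=f"r{i:04d}", age_group=a, education=e,
            marital_status=m, n_children=k,
            ever_alcohol=al, ever_prison=pr, ever_drug=dr,
        )
        for i, (a, e, m, k, al, pr, dr) in enumerate(
            zip(ages, edus, mars, kids, alcohol, prison, drug)
        )
    ]


@pytest.fixture(scope="session")
def alter_table() -> list[AlterRecord]:
    return make_alter_table()
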