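"""Scale-up point estimator: published values, algebraic laws, sample size."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nsum import (
    NetworkConfig,
    NetworkScaleUp,
    apply_adjustments,
    crude_estimate,
    prevalence,
    required_sample_size,
)
from nsum.survey import Gender, SurveyRespondent

from .conftest import respondents_strategy


def brute_force_crude(respondents, config):
    """Independent oracle: per-respondent explicit summation of the ratio."""
    num = 0.0
    den = 0.0
    for r in respondents:
        num += r.m
        den += config.c_male if r.gender is Gender.MALE else config.c_female
    return num / den * config.t


class TestCrudeEstimate:
    def test_study_aggregates(self, study_model):
        """495 men (degree 90) and 505 women (degree 120) reporting 434
        alters against t = 406,916 scale up to about 1680."""
        est = crude_estimate(study_model.respondents, study_model.config)
        assert est.sum_m == 434
        assert est.sum_c == 105_150
        assert est.e_crude == pytest.approx(434 / 105_150 * 406_916, rel=1e-12)
        assert round(est.e_crude) == 1680

    @pytest.mark.filterwarnings("ignore:no hidden-population alters")
    @given(respondents_strategy(min_size=1, max_size=10))
    def test_matches_brute_force_oracle(self, records):
        config = NetworkConfig()
        est = crude_estimate(records, config)
        assert est.e_crude == pytest.approx(brute_force_crude(records, config), rel=1e-12)

    def test_zero_reports_yields_zero_with_flag(self):
        records = [SurveyRespondent(id="a", gender=Gender.MALE, m=0)]
        with pytest.warns(UserWarning, match="no hidden-population alters"):
            est = crude_estimate(records, NetworkConfig())
        assert est.e_crude == 0
        assert est.zero_reports

    def test_full_network_saturates_population(self):
        config = NetworkConfig(t=1000)
        records = [SurveyRespondent(id="w", gender=Gender.FEMALE, m=120)]
        assert crude_estimate(records, config).e_crude == pytest.approx(1000)

    def test_empty_survey_rejected(self):
        with pytest.raises(ValueError):
            crude_estimate([], NetworkConfig())

    @pytest.mark.filterwarnings("ignore:no hidden-population alters")
    @given(
        respondents_strategy(min_size=1, max_size=15),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_homogeneity_in_degrees_and_population(self, records, k):
        """Scaling every degree by k divides e_crude by k; scaling t by k
        multiplies it by k."""
        base = crude_estimate(records, NetworkConfig()).e_crude
        scaled_c = crude_estimate(records, NetworkConfig().scaled_degrees(k)).e_crude
        assert scaled_c * k == pytest.approx(base, rel=1e-9)
        big_t = NetworkConfig(t=NetworkConfig().t * 10)
        assert crude_estimate(records, big_t).e_crude == pytest.approx(base * 10, rel=1e-9)

    def test_strictly_increasing_in_sum_m(self):
        config = NetworkConfig()
        values = []
        for m in (0, 1, 5, 50):
            records = [SurveyRespondent(id="a", gender=Gender.MALE, m=m),
                       SurveyRespondent(id="b", gender=Gender.FEMALE, m=1)]
            values.append(crude_estimate(records, config).e_crude)
        assert all(a < b for a, b in zip(values, values[1:]))


class TestAdjustments:
    def test_study_adjusted_values(self, study_results):
        """VF = 1/0.45 and PF = 1/0.77 turn the crude 1680 into roughly
        3733 (visibility only), 2182 (popularity only) and 4848 (both)."""
        assert round(study_results.e_vf) == pytest.approx(3733, abs=2)
        assert round(study_results.e_pf) == pytest.approx(2182, abs=2)
        assert round(study_results.e_adjusted) == pytest.approx(4848, abs=2)

    def test_identity_factors_leave_crude_unchanged(self, study_model):
        config = NetworkConfig(vf_point=1, vf_range=(1, 1), pf_point=1, pf_range=(1, 1))
        est = apply_adjustments(crude_estimate(study_model.respondents, config), config)
        assert est.e_adjusted == est.e_crude

    @pytest.mark.filterwarnings("ignore:no hidden-population alters")
    @given(
        respondents_strategy(min_size=1, max_size=10),
        st.floats(min_value=1.0, max_value=3.0),
        st.floats(min_value=1.0, max_value=2.0),
    )
    def test_decomposition_identity(self, records, vf, pf):
        """e_adjusted * e_crude == e_vf * e_pf (pure-product structure)."""
        config = NetworkConfig(vf_point=vf, vf_range=(vf, vf), pf_point=pf, pf_range=(pf, pf))
        est = apply_adjustments(crude_estimate(records, config), config)
        if est.e_crude > 0:
            assert est.e_adjusted == pytest.approx(est.e_vf * est.e_pf / est.e_crude, rel=1e-12)


class TestPrevalence:
    def test_study_prevalence_per_1000(self, study_results, study_config):
        assert prevalence(study_results.estimate, study_config, per=1000) == pytest.approx(
            11.92, abs=0.05
        )

    def test_per_t_returns_adjusted_count(self, study_results, study_config):
        assert prevalence(
            study_results.estimate, study_config, per=study_config.t
        ) == pytest.approx(study_results.e_adjusted)

    def test_invalid_per_rejected(self, study_results, study_config):
        with pytest.raises(ValueError):
            prevalence(study_results.estimate, study_config, per=0)

    def test_unadjusted_estimate_rejected(self, study_model):
        est = crude_estimate(study_model.respondents, study_model.config)
        with pytest.raises(ValueError, match="apply_adjustments"):
            prevalence(est, study_model.config)


class TestRequiredSampleSize:
    def test_study_design_parameters(self):
        """Prevalence 0.015, error 0.008, 95% confidence, 10% nonresponse
        (multiplicative inflation) call for 976 interviews — consistent
        with the study's recruited 1000."""
        n = required_sample_size(0.015, 0.008, confidence=0.95, nonresponse=0.10)
        assert n == 976

    def test_divide_convention_is_larger(self):
        mult = required_sample_size(0.015, 0.008, nonresponse=0.10, inflation="multiply")
        div = required_sample_size(0.015, 0.008, nonresponse=0.10, inflation="divide")
        assert div > mult

    def test_boundary_error_gives_single_interview(self):
        from scipy.stats import norm

        p = 0.3
        d = norm.ppf(0.975) * np.sqrt(p * (1 - p))
        assert required_sample_size(p, d, nonresponse=0.0) == 1

    def test_doubling_error_quarters_n(self):
        n1 = required_sample_size(0.2, 0.01, nonresponse=0.0)
        n2 = required_sample_size(0.2, 0.02, nonresponse=0.0)
        assert n2 == pytest.approx(n1 / 4, abs=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": 0.0, "d": 0.01},
            {"p": 0.5, "d": 0.0},
            {"p": 0.5, "d": 0.01, "confidence": 1.0},
            {"p": 0.5, "d": 0.01, "nonresponse": 1.0},
            {"p": 0.5, "d": 0.01, "inflation": "other"},
        ],
    )
    def test_out_of_range_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            required_sample_size(**kwargs)


class TestModelApi:
    def test_from_dataframe_validates_and_fits(self, study_config):
        df = pd.DataFrame(
            {"id": ["a", "b"], "gender": ["male", "female"], "m": ["1", "2"]}
        )
        res = NetworkScaleUp.from_dataframe(df, study_config).fit()
        assert res.sum_m == 3

    def test_from_counts_reconstructs_aggregates(self, study_config):
        model = NetworkScaleUp.from_counts(495, 505, 434, study_config, seed=7)
        assert model.n_male == 495
        assert model.n_female == 505
        assert sum(r.m for r in model.respondents) == 434

    def test_summary_contains_headline_numbers(self, study_results):
        text = study_results.summary()
        for token in ("1679.5", "4847.1", "11.91", "406916"):
            assert token in text

    def test_to_dict_round_trips_through_json(self, study_results):
        import json

        doc = json.loads(json.dumps(study_results.to_dict()))
        assert doc["sum_m"] == 434
        assert doc["e_adjusted"] == pytest.approx(study_results.e_adjusted)
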