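"""Unit and property tests for the forward model mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from npmodel import (
    AgeGroupRow,
    ModelParams,
    Schedule,
    annual_cancer_probability,
    five_year_probability,
    generations_to_cell_count,
    lifetime_cell_budget,
    p_accumulate,
    poisson_upper_tail,
    predict_incidence_table,
    simple_model_crossing_generation,
    simple_model_probability,
)


def brute_force_upper_tail(q, mean):
    """Independent oracle: 1 minus an explicit pmf sum below the threshold."""
    return 1.0 - sum(
        mean**k / math.factorial(k) * math.exp(-mean) for k in range(q)
    )


class TestPoissonUpperTail:
    @pytest.mark.parametrize(
        "q, mean, expected, rel",
        [
            # deep-tail values from the calibrated human regime
            (118, 45, 1.18e-19, 1e-2),
            (118, 46, 5.86e-19, 1e-2),
            # hand-checked complement: e^-2 * (1 + 2 + 2 + 4/3 + 2/3)
            (5, 2, 1 - math.exp(-2) * (1 + 2 + 2 + 4 / 3 + 2 / 3), 1e-12),
        ],
    )
    def test_values(self, q, mean, expected, rel):
        assert poisson_upper_tail(q, mean) == pytest.approx(expected, rel=rel)

    def test_threshold_zero_is_certain(self):
        assert poisson_upper_tail(0, 7.3) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 5.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(5, -1.0)

    @given(
        q=st.integers(min_value=1, max_value=50),
        mean=st.floats(min_value=0.01, max_value=60),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_pmf_sum(self, q, mean):
        """Tail plus the explicit below-threshold pmf sum is unity."""
        below = float(sum(poisson.pmf(k, mean) for k in range(q)))
        assert poisson_upper_tail(q, mean) + below == pytest.approx(1.0, abs=1e-12)

    @given(
        q=st.integers(min_value=1, max_value=120),
        mean=st.floats(min_value=0.5, max_value=60),
        bump=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_mean_and_threshold(self, q, mean, bump):
        assert poisson_upper_tail(q, mean + bump) >= poisson_upper_tail(q, mean)
        assert poisson_upper_tail(q + 1, mean) <= poisson_upper_tail(q, mean)


class TestPAccumulate:
    def test_first_bracket_is_plain_tail(self):
        assert p_accumulate(None, 45, 118) == pytest.approx(1.18e-19, rel=1e-2)

    def test_later_bracket_is_tail_difference(self):
        assert p_accumulate(45, 46, 118) == pytest.approx(4.69e-19, rel=1e-2)

    def test_no_new_generations_no_probability(self):
        assert p_accumulate(50.0, 50.0, 118) == 0.0

    def test_decreasing_generation_rejected(self):
        with pytest.raises(ValueError):
            p_accumulate(46, 45, 118)

    def test_conditional_and_difference_agree_in_deep_tail(self):
        cond = p_accumulate(45, 46, 118, mode="conditional")
        diff = p_accumulate(45, 46, 118, mode="difference")
        assert cond == pytest.approx(diff, rel=1e-10)

    def test_saturated_tail_is_stable(self):
        # mean far above threshold: nearly all cells already transformed;
        # the conditional form must not blow up on the vanishing denominator
        out = p_accumulate(45, 46, 2)
        assert 0.0 <= out <= 1.0

    @given(
        prev=st.floats(min_value=0.5, max_value=50),
        inc=st.floats(min_value=0.0, max_value=5.0),
        q=st.integers(min_value=1, max_value=80),
    )
    @settings(max_examples=100, deadline=None)
    def test_conditional_probability_in_unit_interval(self, prev, inc, q):
        out = p_accumulate(prev, prev + inc, q)
        assert 0.0 <= out <= 1.0


class TestAnnualAndFiveYear:
    def test_calibrated_human_bracket(self):
        # 65-70 bracket: n=5.61e12, p_total=2.70e-15 -> ~1.5% per year
        assert annual_cancer_probability(5.61e12, 2.7024e-15) == pytest.approx(
            0.015028, rel=1e-2
        )

    def test_zero_probability(self):
        assert annual_cancer_probability(1e13, 0.0) == 0.0

    def test_half_survival_identity(self):
        assert annual_cancer_probability(1.0, math.log(2)) == pytest.approx(0.5)

    @given(
        n=st.floats(min_value=0, max_value=1e14),
        p=st.floats(min_value=0, max_value=1e-12),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_survival_identity(self, n, p):
        """1 - annual equals exp(-n*p) to machine precision."""
        annual = annual_cancer_probability(n, p)
        assert 1.0 - annual == pytest.approx(math.exp(-n * p), rel=1e-15)

    @pytest.mark.parametrize(
        "annual, expected",
        [
            (0.015028, 7.2915),
            (0.0, 0.0),
            (1e-4, 100 * (1 - (1 - 1e-4) ** 5)),
        ],
    )
    def test_five_year_percent(self, annual, expected):
        assert five_year_probability(annual) == pytest.approx(expected, rel=1e-2)

    def test_five_year_small_annual_linearisation(self):
        assert five_year_probability(1e-6) == pytest.approx(500e-6, rel=1e-4)

    def test_five_year_domain(self):
        with pytest.raises(ValueError):
            five_year_probability(1.5)


class TestPredictIncidenceTable:
    def test_reproduces_uk_table_spot_values(self, uk_schedule, human_params):
        table = predict_incidence_table(uk_schedule, human_params)
        pct = {r.label: r.p_cancer_5yr_pct for r in table}
        assert pct["0 ~ 5"] == pytest.approx(0.0525, rel=1e-2)
        assert pct["~ 70"] == pytest.approx(7.2915, rel=1e-2)

    def test_attaches_observed_column(self, uk_schedule, human_params):
        table = predict_incidence_table(uk_schedule, human_params)
        assert table.rows[0].observed_5yr_pct == pytest.approx(0.1028)

    def test_no_transformation_channel_means_zero_incidence(self, uk_schedule):
        # p_c = 0 and a threshold far beyond reachable generations
        table = predict_incidence_table(uk_schedule, ModelParams(0.0, 10_000))
        assert np.all(table.five_year_pct == 0.0)

    def test_unit_interval_invariants(self, uk_schedule, human_params):
        table = predict_incidence_table(uk_schedule, human_params)
        for r in table:
            assert 0.0 <= r.p_cancer_annual <= 1.0
            assert r.p_health_annual + r.p_cancer_annual == pytest.approx(1.0)
            assert 0.0 <= r.p_cancer_5yr_pct <= 100.0


class TestSimpleAggregateModel:
    @pytest.mark.parametrize(
        "p, x, expected",
        [
            (1e-15, 50, 1 - math.exp(-(2.0**50) * 1e-15)),
            (0.0, 17, 0.0),
            (1e-15, 0, 1e-15),
        ],
    )
    def test_probability(self, p, x, expected):
        assert simple_model_probability(p, x) == pytest.approx(expected, rel=1e-6)

    def test_probability_nondecreasing_and_limits_to_one(self):
        probs = [simple_model_probability(1e-15, x) for x in range(70)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 1 - 1e-12

    @pytest.mark.parametrize(
        "p, threshold, expected",
        [
            (1e-15, 0.5, 50),
            (math.log(2) / 2, 0.5, 1),
            (1e-12, 0.5, 40),  # smallest x with 2^x >= ln2/1e-12
        ],
    )
    def test_crossing_generation(self, p, threshold, expected):
        assert simple_model_crossing_generation(p, threshold) == expected


class TestScheduleHelpers:
    @pytest.mark.parametrize(
        "cells, expected", [(2e12, 41), (2, 1), (1e6, 20), (1, 0)]
    )
    def test_generations_to_cell_count(self, cells, expected):
        assert generations_to_cell_count(cells) == expected

    def test_lifetime_cell_budget_rectangle(self):
        rows = tuple(
            AgeGroupRow(f"{5*i}-{5*i+5}", 5 * i, 5 * i + 5, 10.0, 1e12)
            for i in range(4)
        )
        assert lifetime_cell_budget(Schedule(rows)) == pytest.approx(2e13)

    def test_lifetime_cell_budget_uk(self, uk_schedule):
        # arithmetic oracle: 5 x the sum of the 19 printed turnover values
        expected = 5 * sum(r.turnover_per_year for r in uk_schedule)
        assert lifetime_cell_budget(uk_schedule) == pytest.approx(expected)
        assert expected == pytest.approx(2.07e15, rel=1e-2)

    def test_empty_budget(self):
        assert lifetime_cell_budget(()) == 0.0

    def test_schedule_rejects_gaps_and_decreasing_generation(self):
        a = AgeGroupRow("0-5", 0, 5, 45, 1e13)
        gap = AgeGroupRow("10-15", 10, 15, 46, 1e13)
        with pytest.raises(ValueError, match="contiguous"):
            Schedule((a, gap))
        dec = AgeGroupRow("5-10", 5, 10, 44, 1e13)
        with pytest.raises(ValueError, match="non-decreasing"):
            Schedule((a, dec))

    def test_generation_cap_clamps_with_warning(self, caplog):
        a = AgeGroupRow("0-5", 0, 5, 54, 1e13)
        b = AgeGroupRow("5-10", 5, 10, 60, 1e13)
        with caplog.at_level("WARNING"):
            s = Schedule((a, b))
        assert s.rows[1].generation == 55
        assert any("clamp" in rec.message for rec in caplog.records)
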