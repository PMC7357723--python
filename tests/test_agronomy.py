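"""Target-yield setting and the N/P/K rate equations."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from ssnmrice import (
    ResidueManagement,
    Season,
    SeasonParams,
    VarietyInfo,
    default_params,
    k_rate,
    n_rate,
    p_rate,
    set_target_yield,
)
from ssnmrice.agronomy import ConfigurationError, k_removal, p_removal

from .conftest import make_interview

REMOVED = ResidueManagement.REMOVED


def params_with(season=Season.SAMBA, **overrides) -> SeasonParams:
    p = default_params(season)
    return SeasonParams(**{**p.model_dump(), **overrides})  # re-validates


class TestTargetYield:
    @pytest.mark.parametrize(
        "historical, window, expected",
        [
            (4.4, (5.2, 6.2), 5.4),  # plain increment inside the window
            (6.4, (5.5, 6.9), 6.9),  # clamped to the window ceiling
            (3.6, (5.5, 6.9), 5.5),  # clamped up to the window floor
        ],
    )
    def test_increment_then_clamp(self, historical, window, expected):
        iv = make_interview(
            season=Season.SAMBA,
            historical_yield=historical,
            variety=VarietyInfo(name="v", duration=130,
                                baseline_yield_lo=window[0],
                                baseline_yield_hi=window[1]),
        )
        assert set_target_yield(iv, params_with()) == pytest.approx(expected)

    def test_zero_increment_at_window_ceiling_is_identity(self):
        iv = make_interview(
            season=Season.SAMBA, historical_yield=6.2,
            variety=VarietyInfo(name="v", duration=130,
                                baseline_yield_lo=5.2, baseline_yield_hi=6.2))
        p = params_with(target_increment=0.0)
        assert set_target_yield(iv, p) == pytest.approx(6.2)

    def test_never_more_than_max_increment_above_historical(self):
        iv = make_interview(
            season=Season.SAMBA, historical_yield=3.6,
            variety=VarietyInfo(name="v", duration=130,
                                baseline_yield_lo=6.5, baseline_yield_hi=6.9))
        target = set_target_yield(iv, params_with())
        assert target == pytest.approx(3.6 + 2.5)

    def test_never_below_historical(self):
        iv = make_interview(
            season=Season.SAMBA, historical_yield=6.4,
            variety=VarietyInfo(name="v", duration=130,
                                baseline_yield_lo=4.0, baseline_yield_hi=5.0))
        assert set_target_yield(iv, params_with()) == pytest.approx(6.4)

    def test_late_establishment_penalty_applies_after_cutoff(self):
        late = make_interview(establishment_date=datetime.date(2014, 7, 5),
                              sowing_date=datetime.date(2014, 6, 10))
        early = make_interview(establishment_date=datetime.date(2014, 6, 14),
                               sowing_date=datetime.date(2014, 5, 20))
        p = default_params(Season.KURUVAI)
        assert (set_target_yield(early, p) - set_target_yield(late, p)
                == pytest.approx(p.late_penalty))

    def test_no_penalty_by_default_outside_kuruvai(self):
        # late thaladi establishment does not reduce the target
        assert default_params(Season.THALADI).late_establishment_cutoff is None

    def test_season_mismatch_is_configuration_error(self, interview):
        with pytest.raises(ConfigurationError):
            set_target_yield(interview, default_params(Season.SAMBA))

    def test_target_invariant_to_products_and_area(self, interview, kuruvai_params):
        base = set_target_yield(interview, kuruvai_params)
        permuted = make_interview(selected_products=["muriate_of_potash", "dap"],
                                  field_area=2.7)
        assert set_target_yield(permuted, kuruvai_params) == base


class TestNRate:
    @pytest.mark.parametrize(
        "gain, ae, expected",
        [(1.8, 15.0, 120.0), (0.0, 15.0, 0.0), (1.82, 14.0, 130.0)],
    )
    def test_yield_gain_equation(self, gain, ae, expected):
        p = params_with(agronomic_efficiency=ae)
        assert n_rate(5.0 + gain, 5.0, p) == expected

    def test_rejects_negative_gain(self):
        with pytest.raises(ValueError):
            n_rate(4.0, 5.0, params_with())

    def test_rejects_nonpositive_efficiency(self):
        with pytest.raises(ValidationError):
            params_with(agronomic_efficiency=0.0)


class TestPKRates:
    def test_p_rate_full_maintenance_examples(self, samba_params):
        # calibrated removal of 2.59 kg P per Mg with residue removed
        assert p_rate(5.4, REMOVED, samba_params) == 14.0
        assert p_rate(5.8, REMOVED, samba_params) == 15.0
        assert p_rate(0.0, REMOVED, samba_params) == 0.0

    def test_p_rate_lower_when_residue_retained(self, thaladi_params):
        retained = p_rate(5.8, ResidueManagement.RETAINED_COMBINE, thaladi_params)
        removed = p_rate(5.8, REMOVED, thaladi_params)
        assert retained < removed

    def test_k_rate_partial_maintenance(self, kuruvai_params, samba_params):
        assert k_rate(5.4, REMOVED, kuruvai_params) == 30.0
        assert k_rate(5.8, REMOVED, samba_params) == 50.0

    def test_k_rate_floors_at_zero(self, thaladi_params):
        # large residue K input covers removal entirely
        assert k_rate(3.5, ResidueManagement.RETAINED_COMBINE, thaladi_params,
                      residue_k=500.0) == 0.0

    @given(target=st.floats(min_value=0.1, max_value=9.0))
    @settings(max_examples=50, deadline=None)
    def test_p_rate_offsets_removal_at_target(self, target):
        """Full maintenance: the unrounded rate equals removal exactly."""
        p = default_params(Season.SAMBA)
        rate = p_rate(target, REMOVED, p)
        assert abs(rate - p_removal(target, REMOVED, p)) <= 0.5

    @given(lo=st.floats(min_value=3.0, max_value=6.0),
           hi=st.floats(min_value=0.1, max_value=3.0))
    @settings(max_examples=50, deadline=None)
    def test_rates_monotone_in_target(self, lo, hi):
        p = default_params(Season.SAMBA)
        a, b = lo, lo + hi
        assert n_rate(b, 3.0, p) >= n_rate(a, 3.0, p)
        assert p_rate(b, REMOVED, p) >= p_rate(a, REMOVED, p)
        assert k_rate(b, REMOVED, p) >= k_rate(a, REMOVED, p)


class TestKRateOracle:
    def test_grid_agrees_with_balance_identity(self):
        """Brute-force: rearranging the K balance for the fertilizer rate
        must give the implemented rate over a parameter grid."""
        import itertools
        p0 = default_params(Season.KURUVAI)
        targets = [3.0, 4.5, 5.4, 6.0, 7.5]
        irrigation = [0.0, 4.0, 8.0, 25.0]
        drawdown = [-40.0, -30.0, -4.0, 0.0]
        residue = [0.0, 10.0, 50.0]
        for t, irr, dd, res in itertools.product(targets, irrigation,
                                                 drawdown, residue):
            p = p0.model_copy(update={"irrigation_k_input": irr,
                                      "k_drawdown_target": dd})
            removal = t * (p.grain_k_removal + p.straw_k_removal)
            oracle = max(0.0, removal - irr - res + dd)
            assert k_rate(t, REMOVED, p, residue_k=res) == round(oracle)


class TestInterviewValidation:
    def test_historical_yield_window(self):
        with pytest.raises(ValidationError):
            make_interview(historical_yield=2.9)
        with pytest.raises(ValidationError):
            make_interview(historical_yield=8.1)

    def test_zero_area_rejected(self):
        with pytest.raises(ValidationError):
            make_interview(field_area=0.0)

    def test_seedling_age_only_for_transplanted(self):
        from ssnmrice import Establishment
        with pytest.raises(ValidationError):
            make_interview(establishment=Establishment.WET_SEEDED, seedling_age=25)
        with pytest.raises(ValidationError):
            make_interview(seedling_age=None)

    def test_establishment_before_sowing_rejected(self):
        with pytest.raises(ValidationError):
            make_interview(establishment_date=datetime.date(2014, 6, 1))

    def test_straw_k_must_exceed_straw_p(self):
        with pytest.raises(ValidationError):
            params_with(straw_k_removal=0.5)
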