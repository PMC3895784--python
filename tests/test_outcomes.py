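"""Harm-benefit decomposition, hold adjustment, equivalence mortality rate."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from txbenefit import (
    HoldAdjustment,
    MortalityRate,
    NoCatchUpError,
    NoEquivalenceError,
    RelativeRiskProfile,
    Scenario,
    adjust_profile,
    benefit_share,
    decompose,
    equivalence_mr,
    harm_benefit_ratio,
    inflation_factor,
    restricted_auc,
    time_to_equal_life_years,
    time_to_equal_survival,
)

from _oracles import bisect_equal_auc

MR_GRID = (15, 20, 25, 30, 35)


class TestInflationFactor:
    @pytest.mark.parametrize(
        "p,rho,expected", [(0.0, 2.2, 1.0), (0.2, 2.2, 1.24), (0.1, 2.2, 1.12)]
    )
    def test_mixture_factor(self, p, rho, expected):
        assert inflation_factor(p, rho) == pytest.approx(expected, abs=1e-12)

    def test_printed_roundings_of_adjusted_risks(self):
        f = inflation_factor(0.2, 2.2)
        assert round(2.26 * f, 1) == 2.8
        assert round(0.44 * f, 2) == 0.55

    @pytest.mark.parametrize("p,rho", [(-0.1, 2.2), (1.0, 2.2), (0.2, 0.9)])
    def test_domain_errors(self, p, rho):
        with pytest.raises(ValueError):
            inflation_factor(p, rho)

    def test_hold_adjustment_type(self):
        assert HoldAdjustment(0.2, 2.2).factor == pytest.approx(1.24)
        assert HoldAdjustment(0.0, 2.2).factor == 1.0
        with pytest.raises(ValueError):
            HoldAdjustment(0.2, 0.5)


class TestAdjustProfile:
    def test_no_hold_is_identity(self, paper_profile):
        assert adjust_profile(paper_profile, 0.0, 2.2) is paper_profile

    def test_twenty_percent_hold_unrounded_products(self, paper_profile):
        adj = adjust_profile(paper_profile, 0.2, 2.2)
        (d1, r1), (d2, r2), (_, r3) = adj.segments
        assert (d1, d2) == (0.2, 0.8)
        assert r1 == pytest.approx(2.8024, abs=1e-12)
        assert r2 == 1.0  # equal-risk period untouched by default
        assert r3 == pytest.approx(0.5456, abs=1e-12)

    def test_ten_percent_hold(self, paper_profile):
        adj = adjust_profile(paper_profile, 0.1, 2.2)
        assert adj.segments[0][1] == pytest.approx(2.5312, abs=1e-12)
        assert adj.segments[2][1] == pytest.approx(0.4928, abs=1e-12)

    def test_scale_equal_segment_flag(self, paper_profile):
        adj = adjust_profile(paper_profile, 0.2, 2.2, scale_equal_segment=True)
        assert adj.segments[1][1] == pytest.approx(1.24, abs=1e-12)


class TestTimeToEqualLifeYears:
    def test_identity_profile_convention(self, identity_profile):
        assert time_to_equal_life_years(identity_profile, 0.2) == 0.0

    def test_against_quadrature_bisection_oracle(self, paper_profile, tm_profile):
        t1 = time_to_equal_life_years(paper_profile, 0.15)
        assert t1 == pytest.approx(2.551075, abs=2e-4)
        assert t1 == pytest.approx(
            bisect_equal_auc(paper_profile.segments, 0.15, 1.5, 6.0), abs=2e-4
        )
        t2 = time_to_equal_life_years(tm_profile, 0.30)
        assert t2 == pytest.approx(3.002893, abs=2e-4)

    @pytest.mark.parametrize("mr", MR_GRID)
    @pytest.mark.parametrize("preset", ["paper", "table_matching"])
    def test_root_condition_and_divergence_beyond(self, preset, mr):
        profile = RelativeRiskProfile.preset(preset)
        m = mr / 100.0
        t_star = time_to_equal_life_years(profile, m)
        gap = lambda t: restricted_auc("transplant", profile, m, t) - restricted_auc(
            "waitlist", None, m, t
        )
        assert abs(gap(t_star)) <= 1e-10
        # beyond the root the transplant arm pulls ahead, increasingly so
        gaps = [gap(t_star + dt) for dt in (0.5, 1.0, 2.0)]
        assert gaps[0] > 0
        assert gaps[0] < gaps[1] < gaps[2]

    def test_later_than_survival_crossing(self, paper_profile, tm_profile):
        for profile in (paper_profile, tm_profile):
            for m in (0.1, 0.2, 0.35):
                assert time_to_equal_life_years(profile, m) > time_to_equal_survival(
                    profile
                )

    def test_terminal_rr_at_least_one_never_catches_up(self):
        profile = RelativeRiskProfile(((0.5, 2.0), (math.inf, 1.0)))
        with pytest.raises(NoCatchUpError):
            time_to_equal_life_years(profile, 0.2)

    def test_insufficient_longrun_advantage_never_catches_up(self):
        # a huge early deficit that the thin long-run advantage cannot repay
        profile = RelativeRiskProfile(((3.0, 40.0), (math.inf, 0.999)))
        with pytest.raises(NoCatchUpError):
            time_to_equal_life_years(profile, 0.35)


class TestDecompose:
    def test_no_benefit_matches_list_mortality(self):
        d = decompose(Scenario.from_rate(15, 2, preset="paper"))
        assert d.p_no_benefit == pytest.approx(1 - math.exp(-0.3), abs=1e-12)
        assert round(100 * d.p_no_benefit) == 26

    def test_zero_wait_shifts_all_mass_to_transplant_arm(self):
        d = decompose(Scenario.from_rate(25, 0.0))
        assert d.p_no_benefit == 0.0
        assert d.p_harm + d.p_benefit == pytest.approx(1.0, abs=1e-12)

    def test_table_matching_cell_mr30(self):
        d = decompose(Scenario.from_rate(30, 2))
        assert d.p_harm == pytest.approx(0.268984, abs=1e-5)
        assert d.p_benefit == pytest.approx(0.279828, abs=1e-5)

    def test_hold_free_scenario_equals_preadjusted_profile(self, tm_profile):
        # applying the hold adjustment inside decompose() is identical to
        # decomposing a scenario built from the adjusted profile directly
        with_hold = decompose(Scenario.from_rate(20, 2, hold_fraction=0.2))
        adj = adjust_profile(tm_profile, 0.2, 2.2)
        explicit = decompose(
            Scenario(mortality=MortalityRate(20), wait_years=2, profile=adj)
        )
        assert with_hold.p_harm == pytest.approx(explicit.p_harm, abs=1e-15)
        assert with_hold.p_benefit == pytest.approx(explicit.p_benefit, abs=1e-15)

    def test_zero_hold_fraction_identity_downstream(self):
        base = decompose(Scenario.from_rate(25, 3))
        held = decompose(Scenario.from_rate(25, 3, hold_fraction=0.0, hold_rr=2.2))
        assert base == held


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    mr=st.floats(1.0, 60.0),
    w=st.floats(0.0, 10.0),
    preset=st.sampled_from(["paper", "table_matching"]),
    hold=st.sampled_from([0.0, 0.1, 0.2]),
)
def test_decomposition_is_a_probability_distribution(mr, w, preset, hold):
    d = decompose(Scenario.from_rate(mr, w, hold_fraction=hold, preset=preset))
    total = d.p_no_benefit + d.p_harm + d.p_benefit
    assert abs(total - 1.0) <= 1e-12
    for p in (d.p_no_benefit, d.p_harm, d.p_benefit):
        assert 0.0 <= p <= 1.0
    assert d.t_equal_life_years >= d.t_equal_survival


def test_no_benefit_monotone_in_rate_and_wait():
    grid = [decompose(Scenario.from_rate(mr, 2)).p_no_benefit for mr in MR_GRID]
    assert all(b > a for a, b in zip(grid, grid[1:]))
    waits = [decompose(Scenario.from_rate(20, w)).p_no_benefit for w in (0, 1, 2, 4)]
    assert all(b > a for a, b in zip(waits, waits[1:]))
    benefit = [decompose(Scenario.from_rate(20, w)).p_benefit for w in (0, 1, 2, 4)]
    assert all(b < a for a, b in zip(benefit, benefit[1:]))


class TestHarmBenefitRatio:
    @pytest.mark.parametrize("mr", MR_GRID)
    def test_invariant_to_waiting_time(self, mr):
        ratios = [
            harm_benefit_ratio(Scenario.from_rate(mr, w, hold_fraction=0.2))
            for w in (2, 3, 4)
        ]
        assert abs(ratios[0] - ratios[1]) <= 1e-12
        assert abs(ratios[0] - ratios[2]) <= 1e-12

    def test_equivalence_point_gives_unit_ratio(self, tm_profile):
        mr_eq = equivalence_mr(tm_profile, mode="continuous")
        assert harm_benefit_ratio(
            Scenario.from_rate(mr_eq, 2)
        ) == pytest.approx(1.0, abs=1e-8)

    def test_value_at_mr30(self):
        assert harm_benefit_ratio(Scenario.from_rate(30, 2)) == pytest.approx(
            0.96125, abs=1e-4
        )


class TestEquivalenceMR:
    def test_integer_grid_with_twenty_percent_hold(self, tm_profile):
        profile = adjust_profile(tm_profile, 0.2, 2.2)
        assert equivalence_mr(profile, mode="integer_grid", grid=range(15, 36)) == 22

    def test_integer_grid_with_ten_percent_hold(self, tm_profile):
        profile = adjust_profile(tm_profile, 0.1, 2.2)
        assert equivalence_mr(profile, mode="integer_grid", grid=range(15, 36)) == 26

    def test_continuous_mode_unadjusted(self, paper_profile, tm_profile):
        assert equivalence_mr(paper_profile, mode="continuous") == pytest.approx(
            34.6152, abs=1e-3
        )
        assert equivalence_mr(tm_profile, mode="continuous") == pytest.approx(
            30.8179, abs=1e-3
        )
        # consistency: benefit share is exactly one half at the solution
        mr = equivalence_mr(tm_profile, mode="continuous")
        assert benefit_share(tm_profile, mr / 100) == pytest.approx(0.5, abs=1e-9)

    def test_identity_profile_has_no_equivalence(self, identity_profile):
        with pytest.raises(NoEquivalenceError):
            equivalence_mr(identity_profile)

    def test_no_crossing_in_bracket(self, tm_profile):
        with pytest.raises(NoEquivalenceError):
            equivalence_mr(tm_profile, mode="continuous", bracket=(5.0, 10.0))
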