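"""Campaign time accounting, coverage, unmet needs and comparisons."""

import numpy as np
import pytest

from conftest import village_from_local_km
from smcplan.campaign import (
    CampaignConfig,
    CampaignError,
    children_to_treatment_days,
    compare_scenarios,
    coverage_from_counts,
    km_to_days,
    mean_t_ci,
    simulate_campaign,
    time_ledger,
    treatment_minutes,
    unmet_needs,
)
from smcplan.routing import build_distance_matrix, held_karp_path


def _line_itinerary(village):
    return held_karp_path(build_distance_matrix(village))


class TestTreatmentMinutes:
    def test_fixed_models_scale_per_child(self):
        assert treatment_minutes(3, CampaignConfig(treatment_model="optimal_fixed")) == 25.5
        assert treatment_minutes(1, CampaignConfig(treatment_model="current_fixed")) == 12.5
        assert treatment_minutes(0, CampaignConfig()) == 0.0

    @pytest.mark.parametrize("n,lo,hi", [(1, 10, 15), (2, 15, 20), (3, 20, 25)])
    def test_draw_brackets(self, n, lo, hi):
        rng = np.random.default_rng(0)
        config = CampaignConfig(treatment_model="optimal_draws")
        draws = [treatment_minutes(n, config, rng) for _ in range(200)]
        assert min(draws) >= lo and max(draws) <= hi

    def test_beyond_three_children_adds_fixed_increment(self):
        rng = np.random.default_rng(1)
        config = CampaignConfig(treatment_model="optimal_draws")
        d5 = treatment_minutes(5, config, rng)
        assert 20 + 2 * 8.5 <= d5 <= 25 + 2 * 8.5

    def test_three_child_draw_mean_near_midpoint(self):
        rng = np.random.default_rng(123)
        config = CampaignConfig(treatment_model="optimal_draws")
        draws = [treatment_minutes(3, config, rng) for _ in range(10_000)]
        assert 22.3 <= np.mean(draws) <= 22.7


class TestTimeConversions:
    @pytest.mark.parametrize("km,days", [(20.0, 0.83), (31.0, 1.29), (0.0, 0.0)])
    def test_km_to_days_matches_20min_per_km(self, km, days):
        assert km_to_days(km) == pytest.approx(days, abs=0.005)

    @pytest.mark.parametrize(
        "children,rate,days",
        [(121, 12.5, 3.15), (324, 8.5, 5.74), (0, 8.5, 0.0)],
    )
    def test_children_to_treatment_days(self, children, rate, days):
        assert children_to_treatment_days(children, rate) == pytest.approx(
            days, abs=0.01
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(CampaignError):
            km_to_days(-1.0)


class TestCoverageAndUnmetNeeds:
    @pytest.mark.parametrize(
        "treated,total,pct", [(121, 324, 37.3), (189, 324, 58.3), (0, 50, 0.0)]
    )
    def test_coverage_from_counts(self, treated, total, pct):
        assert coverage_from_counts(treated, total) == pytest.approx(pct, abs=0.05)

    def test_zero_total_rejected(self):
        with pytest.raises(CampaignError):
            coverage_from_counts(0, 0)

    def test_exact_budget_needs_one_pair(self):
        assert unmet_needs(3.0, 1.0, CampaignConfig(campaign_days=4.0)) == 2.0

    @pytest.mark.parametrize(
        "treat,travel,expected,ndigits",
        [(5.74, 1.29, 3.5, 1), (2.58, 1.16, 1.87, 2), (6.55, 1.70, 4.12, 2)],
    )
    def test_reference_workforce_estimates(self, treat, travel, expected, ndigits):
        assert round(unmet_needs(treat, travel), ndigits) == expected


class TestSimulateCampaign:
    def test_ample_budget_covers_everything(self, line_village):
        itinerary = _line_itinerary(line_village)
        config = CampaignConfig(campaign_days=1000.0)
        result = simulate_campaign(line_village, itinerary, config)
        assert result.coverage_pct == 100.0
        assert result.treated_children == line_village.total_children
        assert result.walking_km == pytest.approx(itinerary.total_km)

    def test_hand_computed_half_coverage(self, line_village):
        # 4 households 1 km apart, 1 child each at 8.5 min: serving 2
        # households needs 17 min treatment + 20 min walking = 37 min
        itinerary = _line_itinerary(line_village)
        budget_days = 37.0 / 480.0
        config = CampaignConfig(chw_pairs=1.0, campaign_days=budget_days)
        result = simulate_campaign(line_village, itinerary, config)
        assert result.visited_households == 2
        assert result.coverage_pct == pytest.approx(50.0)

    def test_tiny_budget_visits_nothing_after_first_unaffordable(self, line_village):
        itinerary = _line_itinerary(line_village)
        config = CampaignConfig(campaign_days=1e-6)
        result = simulate_campaign(line_village, itinerary, config)
        assert result.visited_households == 0
        assert result.coverage_pct == 0.0

    def test_coverage_monotone_in_budget_and_antitone_in_costs(self, random_village):
        from smcplan.routing import heuristic_path

        dm = build_distance_matrix(random_village)
        itinerary = heuristic_path(dm, seed=0)
        base = dict(campaign_days=1.0, treatment_model="optimal_fixed", seed=0)
        cov = lambda **kw: simulate_campaign(
            random_village, itinerary, CampaignConfig(**{**base, **kw})
        ).coverage_pct
        assert cov(chw_pairs=2.0) >= cov(chw_pairs=1.0) >= cov(chw_pairs=0.5)
        assert cov(campaign_days=2.0) >= cov(campaign_days=1.0)
        assert cov(fixed_min_per_child=12.5) <= cov(fixed_min_per_child=8.5)
        assert cov(walk_min_per_km=40.0) <= cov(walk_min_per_km=20.0)
        for kw in ({}, {"chw_pairs": 0.25}, {"campaign_days": 0.1}):
            assert 0.0 <= cov(**kw) <= 100.0

    def test_workforce_sized_from_unmet_needs_reaches_full_coverage(
        self, random_village
    ):
        from smcplan.routing import heuristic_path

        dm = build_distance_matrix(random_village)
        itinerary = heuristic_path(dm, seed=0)
        probe = CampaignConfig(treatment_model="optimal_fixed")
        needed = unmet_needs(*time_ledger(random_village, itinerary, probe), probe)
        config = CampaignConfig(
            chw_pairs=needed / 2.0, treatment_model="optimal_fixed"
        )
        result = simulate_campaign(random_village, itinerary, config)
        assert result.coverage_pct >= 99.0

    def test_time_never_exceeds_budget_plus_one_household(self, random_village):
        from smcplan.routing import heuristic_path

        dm = build_distance_matrix(random_village)
        itinerary = heuristic_path(dm, seed=0)
        config = CampaignConfig(chw_pairs=0.5, campaign_days=1.0)
        result = simulate_campaign(random_village, itinerary, config)
        assert (
            result.treatment_days + result.travel_days
            <= config.budget_days + 1e-9
        )

    def test_empty_village_rejected(self):
        from smcplan.village import Village
        from smcplan.routing import Itinerary

        with pytest.raises(CampaignError):
            simulate_campaign(
                Village("empty", []),
                Itinerary(order=(), total_km=0.0, exact=True),
                CampaignConfig(),
            )


class TestComparisons:
    def test_visited_households_contrast(self):
        comp = compare_scenarios(87, 242, 136, 242)
        assert comp.chi2 == pytest.approx(19.15, abs=0.01)
        assert comp.p_value < 0.001

    def test_treated_children_contrast(self):
        comp = compare_scenarios(121, 324, 189, 324)
        assert comp.chi2 == pytest.approx(27.76, abs=0.01)
        assert comp.p_value < 0.001

    def test_identical_proportions_give_zero_corrected_statistic(self):
        comp = compare_scenarios(50, 100, 50, 100)
        assert comp.chi2 == 0.0

    def test_uncorrected_option_is_larger_here(self):
        corrected = compare_scenarios(87, 242, 136, 242).chi2
        raw = compare_scenarios(87, 242, 136, 242, correction=False).chi2
        assert raw > corrected

    def test_invalid_counts_rejected(self):
        with pytest.raises(CampaignError):
            compare_scenarios(5, 0, 1, 10)


class TestMeanTCI:
    def test_constant_values_zero_width(self):
        mean, lo, hi = mean_t_ci([4.0, 4.0, 4.0])
        assert (mean, lo, hi) == (4.0, 4.0, 4.0)

    def test_closed_form_three_values(self):
        mean, lo, hi = mean_t_ci([1.0, 2.0, 3.0], level=0.95)
        assert mean == pytest.approx(2.0)
        assert hi - mean == pytest.approx(2.484, abs=0.001)

    def test_interval_symmetric_about_mean(self):
        rng = np.random.default_rng(0)
        mean, lo, hi = mean_t_ci(rng.normal(10, 2, size=30))
        assert lo <= mean <= hi
        assert hi - mean == pytest.approx(mean - lo)

    def test_too_few_values_rejected(self):
        with pytest.raises(CampaignError):
            mean_t_ci([1.0])
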