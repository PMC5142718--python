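"""Stage-probability chain, scenario decompositions and the loss grid."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fecundmix.cohort_model import logit10_to_prob
from fecundmix.mortality_bounds import (
    SCENARIOS,
    InfeasibleScenarioError,
    StageProbabilities,
    StudyOutcome,
    crude_fecundability,
    decompose_under_scenario,
    live_birth_probability,
    loss_before_live_birth_range,
    scenario_table,
    stage_losses,
    summary_table,
)
from fecundmix.published import ALL_STUDIES


def outcomes():
    return [
        StudyOutcome(
            name=s.name,
            fec_hcg=logit10_to_prob(s.logit_fec_hcg_fert),
            pi_clin=logit10_to_prob(s.logit_pi_clin),
            pi_lb=live_birth_probability(s.live_births, s.eligible_clinical_pregnancies),
        )
        for s in ALL_STUDIES
    ]


class TestOutcomeArithmetic:
    @pytest.mark.parametrize(
        "births, eligible, expected",
        [(136, 155, 0.877), (79, 100, 0.790), (0, 50, 0.0)],
    )
    def test_live_birth_probability(self, births, eligible, expected):
        assert live_birth_probability(births, eligible) == pytest.approx(expected, abs=5e-4)

    def test_live_birth_probability_domain(self):
        with pytest.raises(ValueError):
            live_birth_probability(1, 0)
        with pytest.raises(ValueError):
            live_birth_probability(10, 5)

    @pytest.mark.parametrize(
        "successes, cycles, expected_pct",
        [(136, 707, 19.2), (373 + 31, 1561, 25.9), (0, 100, 0.0)],
    )
    def test_crude_fecundability(self, successes, cycles, expected_pct):
        assert 100 * crude_fecundability(successes, cycles) == pytest.approx(
            expected_pct, abs=0.05
        )

    def test_crude_fecundability_domain(self):
        with pytest.raises(ValueError):
            crude_fecundability(1, 0)


class TestStageLosses:
    def test_high_implantation_scenario_losses(self):
        losses = stage_losses(0.90, logit10_to_prob(0.558), 136 / 155)
        assert losses.before_implantation == pytest.approx(10.0, abs=0.05)
        assert losses.before_clinical == pytest.approx(29.5, abs=0.05)
        # full-precision chaining gives 38.15; the printed 38.2 reflects
        # pre-rounded intermediates, so compare at the rounding margin
        assert losses.before_live_birth == pytest.approx(38.2, abs=0.11)

    def test_perfect_stages_lose_nothing(self):
        losses = stage_losses(1.0, 1.0, 1.0)
        assert (
            losses.before_implantation
            == losses.before_clinical
            == losses.before_live_birth
            == losses.implantation_to_birth
            == 0.0
        )

    def test_implantation_to_birth_loss_needs_full_precision(self):
        # 34.2% only emerges if pi_CLIN is chained unrounded
        losses = stage_losses(0.9, logit10_to_prob(0.488), 373 / 428)
        assert losses.implantation_to_birth == pytest.approx(34.2, abs=0.05)

    @given(
        pi_hcg=st.floats(min_value=0.05, max_value=1.0),
        pi_clin=st.floats(min_value=0.05, max_value=1.0),
        pi_lb=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_losses_grow_along_the_chain(self, pi_hcg, pi_clin, pi_lb):
        losses = stage_losses(pi_hcg, pi_clin, pi_lb)
        assert 0 <= losses.before_implantation <= losses.before_clinical
        assert losses.before_clinical <= losses.before_live_birth <= 100


class TestDecomposition:
    def test_equal_split_matches_printed_value(self):
        res = decompose_under_scenario(logit10_to_prob(-0.118), 0.80, "equal_fert_hcg")
        assert res.probabilities.pi_fert == pytest.approx(0.735, abs=5e-4)
        assert res.probabilities.pi_hcg == pytest.approx(0.735, abs=5e-4)

    def test_everything_perfect_upstream_bounds_implantation_loss(self):
        # all upstream probabilities at 1 makes FEC_HCG a floor for pi_HCG
        res = decompose_under_scenario(0.462, 1.0, "pi_fert_fixed", 1.0)
        assert res.probabilities.pi_hcg == pytest.approx(0.462)
        assert 100 * (1 - res.probabilities.pi_hcg) == pytest.approx(53.8)

    def test_saturated_product_forces_perfect_implantation(self):
        res = decompose_under_scenario(0.8, 0.8, "pi_fert_fixed", 1.0)
        assert res.probabilities.pi_hcg == pytest.approx(1.0)

    @given(
        fec=st.floats(min_value=0.05, max_value=0.6),
        pi_soc=st.floats(min_value=0.65, max_value=1.0),
        scenario=st.sampled_from(SCENARIOS),
    )
    def test_remultiplication_recovers_fecundability(self, fec, pi_soc, scenario):
        try:
            res = decompose_under_scenario(fec, pi_soc, scenario, 0.9)
        except InfeasibleScenarioError:
            return
        p = res.probabilities
        assert p.pi_soc * p.pi_fert * p.pi_hcg == pytest.approx(fec, abs=1e-12)

    def test_infeasible_scenario_names_the_constraint(self):
        with pytest.raises(InfeasibleScenarioError, match="pi_SOC"):
            decompose_under_scenario(0.9, 0.5, "equal_fert_hcg")
        with pytest.raises(InfeasibleScenarioError, match="pi_HCG"):
            decompose_under_scenario(0.75, 0.8, "pi_fert_fixed", 0.9)


class TestChainProbabilities:
    def test_fecundability_chain_products(self):
        chain = StageProbabilities(0.8, 0.9, 0.7, 0.8, 0.85)
        assert chain.fec_tot == pytest.approx(0.72)
        assert chain.fec_hcg == pytest.approx(0.504)
        assert chain.fec_clin == pytest.approx(0.4032)
        assert chain.fec_lb == pytest.approx(0.34272)

    def test_unknown_stage_propagates_as_none(self):
        chain = StageProbabilities(pi_soc=0.8, pi_hcg=0.7)
        assert chain.fec_tot is None and chain.fec_hcg is None


# Table of printed loss percentages (study x scenario grid), frozen for
# comparison at the 0.1-unit presentation-rounding margin.
PRINTED_GRID = {
    ("wilcox", "pi_hcg_fixed"): (10.0, 29.5, 38.2),
    ("wilcox", "equal_fert_hcg"): (26.5, 42.4, 49.5),
    ("wilcox", "pi_fert_fixed"): (40.0, 53.0, 58.7),
    ("zinaman", "pi_hcg_fixed"): (10.0, 21.3, 37.8),
    ("zinaman", "equal_fert_hcg"): (31.0, 39.6, 52.3),
    ("zinaman", "pi_fert_fixed"): (47.1, 53.7, 63.4),
    ("wang", "pi_hcg_fixed"): (10.0, 32.1, 40.8),
    ("wang", "equal_fert_hcg"): (24.0, 42.7, 50.0),
    ("wang", "pi_fert_fixed"): (35.8, 51.6, 57.8),
}

PRINTED_SUMMARY = {
    # fec_hcg, fec_clin, pi_clin, pi_lb, implantation-to-birth loss
    "wilcox": (0.432, 0.339, 0.783, 0.877, 31.3),
    "zinaman": (0.381, 0.333, 0.875, 0.790, 30.9),
    "wang": (0.462, 0.349, 0.754, 0.871, 34.2),
}


class TestGrids:
    def test_summary_table_reproduces_printed_chain_values(self):
        frame = summary_table(outcomes()).set_index("study")
        for study, (fec_hcg, fec_clin, pi_clin, pi_lb, loss) in PRINTED_SUMMARY.items():
            row = frame.loc[study]
            assert row["fec_hcg"] == pytest.approx(fec_hcg, abs=1.5e-3)
            assert row["fec_clin"] == pytest.approx(fec_clin, abs=1.5e-3)
            assert row["pi_clin"] == pytest.approx(pi_clin, abs=1.5e-3)
            assert row["pi_lb"] == pytest.approx(pi_lb, abs=1.5e-3)
            assert row["loss_implantation_to_birth"] == pytest.approx(loss, abs=0.11)

    def test_scenario_grid_reproduces_printed_loss_rows(self):
        grid = scenario_table(outcomes(), pi_soc=0.80, fixed=0.9).set_index(
            ["study", "scenario"]
        )
        for key, (impl, clin, birth) in PRINTED_GRID.items():
            row = grid.loc[key]
            assert row["loss_before_implantation"] == pytest.approx(impl, abs=0.11)
            assert row["loss_before_clinical"] == pytest.approx(clin, abs=0.11)
            assert row["loss_before_live_birth"] == pytest.approx(birth, abs=0.11)

    def test_total_loss_range_spans_the_plausible_band(self):
        grid = scenario_table(outcomes(), pi_soc=0.80, fixed=0.9)
        lo, hi = loss_before_live_birth_range(grid)
        assert lo == pytest.approx(37.8, abs=0.11)
        assert hi == pytest.approx(63.4, abs=0.11)
        # the derived band brackets the 40-60% plausibility statement
        assert lo < 40 < 60 < hi

    def test_pi_soc_has_no_default(self):
        with pytest.raises(TypeError):
            scenario_table(outcomes())  # pi_soc must be supplied explicitly

    def test_infeasible_cells_annotated_not_fatal(self):
        bad = [StudyOutcome("impossible", fec_hcg=0.9, pi_clin=0.8, pi_lb=0.9)]
        grid = scenario_table(bad, pi_soc=0.8, fixed=0.9)
        assert grid["note"].str.contains("infeasible").all()
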