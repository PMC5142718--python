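"""ELS objective, multistart fitting, reparameterisation, Wald intervals."""

import dataclasses
import math

import numpy as np
import pytest

from fecundmix.cohort_model import ObservationPair, ParameterSet
from fecundmix.els_fit import (
    Convergence,
    FitOptions,
    FitResult,
    ModelSpec,
    canonicalize_parameters,
    els_objective,
    fit_model,
    parameter_intervals,
)
from fecundmix.published import WILCOX
from fecundmix.synthetic_data import expected_counts


def pairs_from(residuals, predictions):
    return [
        ObservationPair("preg_clin", i + 1, f + r, f)
        for i, (r, f) in enumerate(zip(residuals, predictions))
    ]


def params_with(sigma=1.0, gamma=0.0):
    return ParameterSet(
        logit_fec_hcg=(0.0,), logit_pi_clin=(0.0,), log_sigma=math.log(sigma), gamma=gamma
    )


class TestObjective:
    def test_unit_residuals_homoscedastic(self):
        # (1 + 1)/1 + 2*ln 1 = 2
        pairs = pairs_from([1.0, -1.0], [10.0, 10.0])
        assert els_objective(params_with(sigma=1.0), pairs) == pytest.approx(2.0)

    def test_pure_variance_penalty(self):
        pairs = pairs_from([0.0], [10.0])
        assert els_objective(params_with(sigma=2.0), pairs) == pytest.approx(math.log(4.0))

    def test_power_variance_matches_brute_force(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(1.0, 50.0, size=12)
        r = rng.normal(0.0, 3.0, size=12)
        sigma = 0.7
        pairs = pairs_from(r, f)
        brute = sum(
            (ri**2) / (sigma**2 * fi**2) + math.log(sigma**2 * fi**2)
            for ri, fi in zip(r, f)
        )
        value = els_objective(params_with(sigma=sigma, gamma=2.0), pairs)
        assert value == pytest.approx(brute, abs=1e-12)

    def test_convention_constant_cancels_in_differences(self):
        """Adding n*c to every objective (e.g. the ln 2pi term) cannot move a LRT."""
        pairs = pairs_from([1.0, -2.0, 0.5], [5.0, 8.0, 3.0])
        a = els_objective(params_with(sigma=1.0), pairs)
        b = els_objective(params_with(sigma=2.0), pairs)
        n, c = len(pairs), math.log(2 * math.pi)
        assert (a + n * c) - (b + n * c) == pytest.approx(a - b, abs=1e-12)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            els_objective(params_with(), [])


class TestFitModel:
    def test_zero_residual_dataset_recovers_generating_logits(self, wilcox_params):
        """At a noise-free dataset the generating parameters are the exact optimum."""
        dataset = expected_counts(wilcox_params, WILCOX.design())
        options = FitOptions(seed=4, fixed_log_sigma=math.log(0.5), fixed_gamma=0.0)
        fit = fit_model(dataset, "0", options)
        est = fit.estimates
        assert est.logit_fert1 == pytest.approx(wilcox_params.logit_fert1, abs=1e-4)
        assert est.logit_fec_hcg == pytest.approx(wilcox_params.logit_fec_hcg, abs=1e-4)
        assert est.logit_pi_clin[0] == pytest.approx(wilcox_params.logit_pi_clin[0], abs=1e-4)

    def test_fit_is_deterministic_given_options(self, sim_dataset_small):
        options = FitOptions(seed=9, n_starts=3)
        a = fit_model(sim_dataset_small, "1", options)
        b = fit_model(sim_dataset_small, "1", options)
        assert a.objective_value == b.objective_value
        assert np.array_equal(a.x, b.x)

    def test_gradient_vanishes_and_hessian_spd_at_optimum(self, fit0_small):
        assert fit0_small.convergence.gradient_norm < 1e-2
        assert fit0_small.standard_errors is not None  # Hessian was positive definite
        assert all(se > 0 for se in fit0_small.standard_errors.values())

    def test_bookkeeping_of_observations_and_parameters(self, fit0_small, sim_dataset_small):
        # 6 cohort sizes + 7 hCG + 7 clinical + 1 long-run count
        assert fit0_small.n_observations == 21
        assert fit0_small.n_parameters == 6
        assert fit0_small.degrees_of_freedom == 15
        assert len(fit0_small.pairs) == 21

    def test_nesting_ladder_of_objectives(self, suite_small):
        obj = {name: suite_small.fits[name].objective_value for name in ("1", "0", "2", "3", "4")}
        assert obj["1"] >= obj["0"] - 1e-6
        assert obj["0"] >= obj["2"] - 1e-6
        assert obj["2"] >= obj["3"] - 1e-6
        assert obj["4"] >= obj["0"] - 1e-6

    def test_too_few_observations_rejected(self, wilcox_params):
        design = dataclasses.replace(WILCOX.design(), n_cycles=9)
        dataset = expected_counts(wilcox_params, design)
        short = dataclasses.replace(
            dataset, cycles=dataset.cycles[:2], nonpreg_horizon=None, n_initial=dataset.cycles[0].n_start
        )
        with pytest.raises(ValueError, match="observations"):
            fit_model(short, "0")


class TestModel00Reparameterisation:
    def test_objectives_agree_and_eq5_maps_the_estimates(self, sim_dataset_small, fit0_small):
        fit00 = fit_model(
            sim_dataset_small, "00", FitOptions(seed=13), extra_starts=[fit0_small.estimates]
        )
        fit0b = fit_model(
            sim_dataset_small, "0", FitOptions(seed=14), extra_starts=[fit00.estimates]
        )
        assert abs(fit00.objective_value - fit0b.objective_value) < 1e-6
        # FEC_CLIN = FEC_HCG * pi_CLIN maps one parameterisation onto the other
        a, b = fit0b.estimates, fit00.estimates
        assert a.fec_clin[0] == pytest.approx(b.fec_hcg[0] * b.pi_clin[0], abs=1e-4)
        assert a.pi_clin[0] == pytest.approx(b.pi_clin[0], abs=1e-4)


class TestCanonicalOrdering:
    def test_subcohorts_sorted_by_decreasing_fecundability(self):
        scrambled = ParameterSet(
            logit_fec_hcg=(-1.0, 0.2), logit_pi_clin=(0.5,), mixture_logits=(0.3,)
        )
        canon = canonicalize_parameters(scrambled)
        assert canon.logit_fec_hcg == (0.2, -1.0)
        # fractions follow their sub-cohorts
        assert canon.fractions[0] == pytest.approx(scrambled.fractions[1], abs=1e-12)


def minimal_fit(logit, se):
    spec = ModelSpec.from_name("1")
    params = ParameterSet(logit_fec_hcg=(logit,), logit_pi_clin=(0.0,))
    return FitResult(
        model_spec=spec,
        estimates=params,
        x=np.array([logit]),
        param_names=("logit_fec_hcg_1",),
        standard_errors=None if se is None else {"logit_fec_hcg_1": se},
        covariance=None,
        objective_value=0.0,
        n_observations=10,
        n_parameters=1,
        convergence=Convergence("converged", 0, 0.0, 0, (0.0,)),
        pairs=(),
        options=FitOptions(),
    )


class TestIntervals:
    def test_wald_interval_maps_to_probability_scale(self):
        # frozen against a direct evaluation of 10**(0.408 +/- 1.959964*0.085) / (1 + .)
        iv = parameter_intervals(minimal_fit(0.408, 0.085))["logit_fec_hcg_1"]
        assert iv.point == pytest.approx(0.719, abs=5e-4)
        assert iv.lower == pytest.approx(0.635492, abs=1e-5)
        assert iv.upper == pytest.approx(0.789690, abs=1e-5)

    def test_zero_se_collapses_to_the_point(self):
        iv = parameter_intervals(minimal_fit(0.3, 0.0))["logit_fec_hcg_1"]
        assert iv.lower == iv.point == iv.upper

    def test_neutral_logit_gives_interval_symmetric_about_half(self):
        iv = parameter_intervals(minimal_fit(0.0, 0.2))["logit_fec_hcg_1"]
        assert iv.point == pytest.approx(0.5)
        assert iv.upper - 0.5 == pytest.approx(0.5 - iv.lower, abs=1e-12)

    def test_missing_standard_errors_marked_unavailable(self):
        iv = parameter_intervals(minimal_fit(0.3, None))["logit_fec_hcg_1"]
        assert not iv.available
        assert iv.lower is None and iv.upper is None
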