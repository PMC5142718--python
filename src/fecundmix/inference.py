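"""Likelihood-ratio comparison of nested model fits.

Because the ELS objective plays the role of -2 log-likelihood (up to a
data-independent additive constant shared by both fits), the difference
in objective values between a nested null and a richer alternative is
referred to a chi-square distribution with degrees of freedom equal to
the parameter-count difference.

The study suite runs the four standard tests:

=====  ============================================  ===
test   null vs alternative                           dof
=====  ============================================  ===
H1     one fecundability (Model 1) vs two (Model 0)   2
H2     two sub-cohorts (Model 0) vs three (Model 2)   2
H3     shared pi_CLIN (Model 0) vs per-cohort,
       three sub-cohorts (Model 3)                    4
H4     homoscedastic residuals (Model 4) vs free
       gamma (Model 0)                                1
=====  ============================================  ===

Caveat, deliberately reproduced as printed in the field's practice: H1
and H2 test the absence of a mixture component, a boundary hypothesis for
which the naive chi-square reference distribution is conservative; the
p-values are therefore upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .els_fit import (
    FitOptions,
    FitResult,
    ModelSpec,
    embedded_parameters,
    fit_model,
)
from .study_data import StudyDataset

__all__ = [
    "LRTResult",
    "HypothesisSuite",
    "likelihood_ratio_test",
    "hypothesis_suite",
    "is_nested",
]

_NEGATIVE_CHI2_TOL = 1e-6


class NotNestedError(ValueError):
    """The two model specs are not in a null-within-alternative relation."""


class ConvergenceSuspectError(RuntimeError):
    """The alternative fit is worse than the null by more than numerical noise."""


def is_nested(null_spec: ModelSpec, alt_spec: ModelSpec) -> bool:
    """True when every configuration the null allows is available to the alternative.

    The alternative must have at least as many sub-cohorts, at least as
    flexible a pi_CLIN structure and residual model, and strictly more
    parameters.  The Model 0 / Model 00 pair is a pure reparameterisation
    (equal parameter counts) and is *not* nested.
    """
    more_cohorts = null_spec.n_subcohorts <= alt_spec.n_subcohorts
    clin_ok = null_spec.shared_pi_clin or not alt_spec.shared_pi_clin
    gamma_ok = null_spec.gamma_fixed_zero or not alt_spec.gamma_fixed_zero
    return (
        more_cohorts
        and clin_ok
        and gamma_ok
        and alt_spec.n_parameters > null_spec.n_parameters
    )


@dataclass(frozen=True)
class LRTResult:
    null_fit: FitResult
    alt_fit: FitResult
    chi_square: float
    dof: int
    p_value: float

    def __str__(self) -> str:
        return (
            f"LRT: chi2 = {self.chi_square:.2f}, dof = {self.dof}, "
            f"p = {self.p_value:.3g}"
        )


def likelihood_ratio_test(null_fit: FitResult, alt_fit: FitResult) -> LRTResult:
    """Compare two fits of nested models on the identical observation vector.

    ``chi_square`` is the null objective minus the alternative objective;
    values in ``[-1e-6, 0)`` are clipped to 0 (optimiser noise), anything
    more negative raises :class:`ConvergenceSuspectError` because a
    correctly converged alternative can never fit worse — refit with more
    starts (e.g. warm-started from the null via
    :func:`fecundmix.els_fit.embedded_parameters`).
    """
    if not is_nested(null_fit.model_spec, alt_fit.model_spec):
        raise NotNestedError(
            f"{null_fit.model_spec} is not nested in {alt_fit.model_spec}"
        )
    if null_fit.n_observations != alt_fit.n_observations or not np.allclose(
        null_fit.observed_vector, alt_fit.observed_vector
    ):
        raise ValueError("fits compare different observation vectors")
    chi2 = null_fit.objective_value - alt_fit.objective_value
    if chi2 < -_NEGATIVE_CHI2_TOL:
        raise ConvergenceSuspectError(
            f"alternative fit is worse than the null by {-chi2:.3g}; "
            "refit the alternative with more starts or a warm start at the null"
        )
    chi2 = max(chi2, 0.0)
    dof = alt_fit.n_parameters - null_fit.n_parameters
    return LRTResult(
        null_fit=null_fit,
        alt_fit=alt_fit,
        chi_square=chi2,
        dof=dof,
        p_value=float(scipy.stats.chi2.sf(chi2, dof)),
    )


_SUITE = (
    ("H1", "1", "0", "one vs two fecundability sub-cohorts"),
    ("H2", "0", "2", "two vs three fecundability sub-cohorts"),
    ("H3", "0", "3", "shared vs per-sub-cohort pi_CLIN (three sub-cohorts)"),
    ("H4", "4", "0", "homoscedastic vs power-of-the-mean residuals"),
)


@dataclass(frozen=True)
class HypothesisSuite:
    fits: Mapping[str, FitResult]        # keyed by model name "0".."4"
    tests: Mapping[str, LRTResult]       # keyed by "H1".."H4"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, null_name, alt_name, description in _SUITE:
            t = self.tests[label]
            rows.append(
                {
                    "hypothesis": label,
                    "description": description,
                    "null_model": null_name,
                    "alt_model": alt_name,
                    "chi_square": t.chi_square,
                    "dof": t.dof,
                    "p_value": t.p_value,
                }
            )
        return pd.DataFrame(rows)


def hypothesis_suite(dataset: StudyDataset, options: FitOptions | None = None) -> HypothesisSuite:
    """Fit Models 0-4 on one study and run the four nested-model tests.

    Each alternative model receives a warm start embedding the relevant
    fitted null (and Model 3 additionally the Model 2 fit), so test
    statistics are non-negative by construction rather than by luck.
    Fit errors propagate annotated with the hypothesis label.
    """
    options = options or FitOptions()
    fits: dict[str, FitResult] = {}

    def fit(name: str, warm_from: tuple[str, ...] = ()) -> FitResult:
        spec = ModelSpec.from_name(name)
        extra = [
            embedded_parameters(fits[src].estimates, spec)
            for src in warm_from
            if src in fits
        ]
        try:
            fits[name] = fit_model(dataset, spec, options, extra_starts=extra)
        except Exception as exc:
            raise RuntimeError(f"fitting Model {name} failed: {exc}") from exc
        return fits[name]

    fit("1")
    fit("4")
    fit("0", warm_from=("1", "4"))
    fit("2", warm_from=("0",))
    fit("3", warm_from=("0", "2"))

    tests: dict[str, LRTResult] = {}
    for label, null_name, alt_name, _ in _SUITE:
        try:
            tests[label] = likelihood_ratio_test(fits[null_name], fits[alt_name])
        except Exception as exc:
            raise RuntimeError(f"{label} ({null_name} vs {alt_name}): {exc}") from exc
    return HypothesisSuite(fits=fits, tests=tests)
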