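"""Published summary values of the three prospective hCG conception studies.

These constants are the *printed* inputs the bounds calculus and the
synthetic-study conditions are built from: study designs (starting cohort
size, reported cycles, which cycles had hCG assays, long-run follow-up),
the best-fit two-sub-cohort model estimates on the base-10 logit scale
with their standard errors, and the pregnancy outcome counts behind
``pi_LB`` and the crude fecundability bounds.

They are reference data, not fitted output of this package: refitting the
original per-cycle tables requires the deposited study files, which are
not distributed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort_model import ParameterSet, StudyDesign

__all__ = ["PublishedStudy", "WILCOX", "ZINAMAN", "WANG", "ALL_STUDIES"]


@dataclass(frozen=True)
class PublishedStudy:
    """Printed design, estimates and outcome counts for one study."""

    name: str
    n_initial: int
    n_cycles: int
    hcg_observed_cycles: frozenset[int]
    horizon: int | None                 # long-run follow-up, in cycles
    nonpreg_count: int | None           # never-pregnant women at the horizon

    # two-sub-cohort model estimates, base-10 logit scale
    logit_fert1: float
    logit_fec_hcg_fert: float
    logit_fec_hcg_subf: float
    logit_fec_clin_fert: float
    logit_fec_clin_subf: float
    logit_pi_clin: float
    sigma: float
    gamma: float
    se_logit_fert1: float
    se_logit_fec_hcg_fert: float
    se_logit_pi_clin: float
    objective_value: float              # reported ELS at the optimum
    n_observations: int

    # pregnancy outcome counts
    live_births: int
    eligible_clinical_pregnancies: int  # excl. lost-to-follow-up / induced abortion
    total_cycles: int
    ongoing_pregnancies: int = 0

    def parameter_set(self) -> ParameterSet:
        """The printed estimates as a two-sub-cohort :class:`ParameterSet`."""
        return ParameterSet(
            logit_fec_hcg=(self.logit_fec_hcg_fert, self.logit_fec_hcg_subf),
            logit_pi_clin=(self.logit_pi_clin,),
            mixture_logits=(self.logit_fert1,),
            log_sigma=math.log(self.sigma),
            gamma=self.gamma,
        )

    def design(
        self,
        observed_fin: tuple[float, ...] | None = None,
        observed_drop: tuple[float, ...] | None = None,
    ) -> StudyDesign:
        """The study design; finisher/dropout streams default to zero
        (the per-cycle exit counts live in the deposited tables only)."""
        zeros = (0.0,) * self.n_cycles
        return StudyDesign(
            n_initial=self.n_initial,
            n_cycles=self.n_cycles,
            observed_fin=observed_fin or zeros,
            observed_drop=observed_drop or zeros,
            hcg_observed_cycles=self.hcg_observed_cycles,
            horizon=self.horizon,
        )


WILCOX = PublishedStudy(
    name="wilcox",
    n_initial=221,
    n_cycles=9,
    hcg_observed_cycles=frozenset(range(1, 10)),
    horizon=24,
    nonpreg_count=14,
    logit_fert1=0.408,
    logit_fec_hcg_fert=-0.118,
    logit_fec_hcg_subf=-1.087,
    logit_fec_clin_fert=-0.291,
    logit_fec_clin_subf=-1.200,
    logit_pi_clin=0.558,
    sigma=0.437,
    gamma=1.26,
    se_logit_fert1=0.085,
    se_logit_fec_hcg_fert=0.066,
    se_logit_pi_clin=0.099,
    objective_value=52.6707,
    n_observations=27,
    live_births=136,
    eligible_clinical_pregnancies=155,
    total_cycles=707,
)

ZINAMAN = PublishedStudy(
    name="zinaman",
    n_initial=200,
    n_cycles=12,
    hcg_observed_cycles=frozenset(range(1, 4)),
    horizon=None,
    nonpreg_count=None,
    logit_fert1=0.529,
    logit_fec_hcg_fert=-0.211,
    logit_fec_hcg_subf=-1.598,
    logit_fec_clin_fert=-0.301,
    logit_fec_clin_subf=-1.657,
    logit_pi_clin=0.845,
    sigma=1.250,
    gamma=0.47,
    se_logit_fert1=0.145,
    se_logit_fec_hcg_fert=0.049,
    se_logit_pi_clin=0.165,
    objective_value=73.0862,
    n_observations=26,
    live_births=79,
    eligible_clinical_pregnancies=100,
    total_cycles=432,
)

WANG = PublishedStudy(
    name="wang",
    n_initial=518,
    n_cycles=14,
    hcg_observed_cycles=frozenset(range(1, 15)),
    horizon=None,
    nonpreg_count=None,
    logit_fert1=1.194,
    logit_fec_hcg_fert=-0.066,
    logit_fec_hcg_subf=-1.304,
    logit_fec_clin_fert=-0.271,
    logit_fec_clin_subf=-1.431,
    logit_pi_clin=0.488,
    sigma=0.870,
    gamma=0.84,
    se_logit_fert1=0.167,
    se_logit_fec_hcg_fert=0.029,
    se_logit_pi_clin=0.043,
    objective_value=119.209,
    n_observations=41,
    live_births=373,
    eligible_clinical_pregnancies=428,
    total_cycles=1561,
    ongoing_pregnancies=31,
)

ALL_STUDIES = (WILCOX, ZINAMAN, WANG)
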