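"""Stage-wise reproductive-success chain and embryo-mortality bounds.

A live birth requires five stages in sequence, each with a conditional
probability of success: sperm-ovum co-localisation (``pi_SOC``),
fertilisation (``pi_FERT``), implantation, detectable as a rise in hCG
(``pi_HCG``), clinical recognition (``pi_CLIN``) and survival to live
birth (``pi_LB``).  Cumulative products give the four fecundabilities

    FEC_TOT  = pi_SOC * pi_FERT
    FEC_HCG  = FEC_TOT * pi_HCG
    FEC_CLIN = FEC_HCG * pi_CLIN
    FEC_LB   = FEC_CLIN * pi_LB

Pre-implantation loss, ``1 - pi_HCG``, is not observable from hCG data:
the studies only identify ``FEC_HCG`` (for the fertile sub-cohort), which
pins down the *product* ``pi_FERT * pi_HCG = FEC_HCG / pi_SOC`` once a
value is assumed for ``pi_SOC``.  The scenario calculus resolves that
product into its factors under three assumptions (high implantation,
equal split, high fertilisation) and converts each resolution into
cumulative loss percentages of fertilised eggs.

``pi_SOC`` is always an explicit argument, never a default: it is an
assumption, not an estimate.  All chaining is done at full precision;
round only for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "SCENARIOS",
    "StageProbabilities",
    "StageLosses",
    "ScenarioResult",
    "StudyOutcome",
    "InfeasibleScenarioError",
    "live_birth_probability",
    "crude_fecundability",
    "stage_losses",
    "decompose_under_scenario",
    "scenario_table",
    "summary_table",
    "loss_before_live_birth_range",
]

#: scenario labels, in the presentation order of the loss grid
SCENARIOS = ("pi_hcg_fixed", "equal_fert_hcg", "pi_fert_fixed")


class InfeasibleScenarioError(ValueError):
    """A scenario would require a probability above 1; names the constraint."""


def _check_prob(value: float, name: str, *, allow_one: bool = True) -> float:
    value = float(value)
    hi_ok = value <= 1.0 if allow_one else value < 1.0
    if not (math.isfinite(value) and 0.0 < value and hi_ok):
        raise ValueError(f"{name} must be a probability in (0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class StageProbabilities:
    """Conditional success probabilities of the five stages; ``None`` = unknown."""

    pi_soc: float | None = None
    pi_fert: float | None = None
    pi_hcg: float | None = None
    pi_clin: float | None = None
    pi_lb: float | None = None

    def __post_init__(self):
        for name in ("pi_soc", "pi_fert", "pi_hcg", "pi_clin", "pi_lb"):
            value = getattr(self, name)
            if value is not None:
                _check_prob(value, name)

    def _product(self, *names: str) -> float | None:
        out = 1.0
        for name in names:
            value = getattr(self, name)
            if value is None:
                return None
            out *= value
        return out

    @property
    def fec_tot(self) -> float | None:
        return self._product("pi_soc", "pi_fert")

    @property
    def fec_hcg(self) -> float | None:
        return self._product("pi_soc", "pi_fert", "pi_hcg")

    @property
    def fec_clin(self) -> float | None:
        return self._product("pi_soc", "pi_fert", "pi_hcg", "pi_clin")

    @property
    def fec_lb(self) -> float | None:
        return self._product("pi_soc", "pi_fert", "pi_hcg", "pi_clin", "pi_lb")


def live_birth_probability(live_births: float, eligible_clinical_pregnancies: float) -> float:
    """``pi_LB``: live births over clinical pregnancies with known outcome
    (pregnancies lost to follow-up and induced abortions are excluded from
    the denominator by the caller)."""
    if eligible_clinical_pregnancies <= 0:
        raise ValueError("eligible clinical pregnancy count must be positive")
    if not 0 <= live_births <= eligible_clinical_pregnancies:
        raise ValueError("live births must lie between 0 and the eligible count")
    return live_births / eligible_clinical_pregnancies


def crude_fecundability(successes: float, cycles: float) -> float:
    """Naive per-cycle success probability: outcomes over observed cycles.

    A lower bound for the fecundability of normally fertile couples, since
    the cycle count includes sub-fertile couples and imperfectly timed
    cycles.
    """
    if cycles <= 0:
        raise ValueError("cycle count must be positive")
    if not 0 <= successes <= cycles:
        raise ValueError("successes must lie between 0 and the cycle count")
    return successes / cycles


@dataclass(frozen=True)
class StageLosses:
    """Cumulative losses of fertilised eggs, as percentages."""

    before_implantation: float
    before_clinical: float
    before_live_birth: float
    implantation_to_birth: float


def stage_losses(pi_hcg: float, pi_clin: float, pi_lb: float) -> StageLosses:
    """Loss percentages along the chain from fertilisation.

    ``100*(1 - pi_HCG)`` of fertilised eggs are lost before implantation,
    ``100*(1 - pi_HCG*pi_CLIN)`` before clinical recognition and
    ``100*(1 - pi_HCG*pi_CLIN*pi_LB)`` before live birth; the
    implantation-to-birth loss ``100*(1 - pi_CLIN*pi_LB)`` conditions on
    implantation having happened.
    """
    pi_hcg = _check_prob(pi_hcg, "pi_hcg")
    pi_clin = _check_prob(pi_clin, "pi_clin")
    pi_lb = _check_prob(pi_lb, "pi_lb")
    return StageLosses(
        before_implantation=100.0 * (1.0 - pi_hcg),
        before_clinical=100.0 * (1.0 - pi_hcg * pi_clin),
        before_live_birth=100.0 * (1.0 - pi_hcg * pi_clin * pi_lb),
        implantation_to_birth=100.0 * (1.0 - pi_clin * pi_lb),
    )


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    probabilities: StageProbabilities
    losses: StageLosses | None = None


def decompose_under_scenario(
    fec_hcg: float,
    pi_soc: float,
    scenario: str,
    fixed_value: float | None = None,
    *,
    pi_clin: float | None = None,
    pi_lb: float | None = None,
) -> ScenarioResult:
    """Split ``FEC_HCG`` into stage probabilities under one assumption.

    The identifiable product is ``pi_FERT * pi_HCG = fec_hcg / pi_soc``.
    Scenarios: ``"equal_fert_hcg"`` sets both factors to its square root;
    ``"pi_fert_fixed"`` fixes ``pi_FERT = fixed_value`` and derives
    ``pi_HCG``; ``"pi_hcg_fixed"`` the converse.  When ``pi_clin`` and
    ``pi_lb`` are supplied the stage-loss percentages are attached.
    """
    fec_hcg = _check_prob(fec_hcg, "fec_hcg")
    pi_soc = _check_prob(pi_soc, "pi_soc")
    product = fec_hcg / pi_soc
    if product > 1.0:
        raise InfeasibleScenarioError(
            f"pi_FERT * pi_HCG = FEC_HCG / pi_SOC = {product:.4f} > 1; "
            f"pi_SOC = {pi_soc} is too small for FEC_HCG = {fec_hcg}"
        )
    if scenario == "equal_fert_hcg":
        pi_fert = pi_hcg = math.sqrt(product)
    elif scenario == "pi_fert_fixed":
        if fixed_value is None:
            raise ValueError("scenario 'pi_fert_fixed' needs fixed_value")
        pi_fert = _check_prob(fixed_value, "pi_fert")
        pi_hcg = product / pi_fert
        if pi_hcg > 1.0:
            raise InfeasibleScenarioError(
                f"pi_HCG = {pi_hcg:.4f} > 1; pi_FERT = {pi_fert} is below the product {product:.4f}"
            )
    elif scenario == "pi_hcg_fixed":
        if fixed_value is None:
            raise ValueError("scenario 'pi_hcg_fixed' needs fixed_value")
        pi_hcg = _check_prob(fixed_value, "pi_hcg")
        pi_fert = product / pi_hcg
        if pi_fert > 1.0:
            raise InfeasibleScenarioError(
                f"pi_FERT = {pi_fert:.4f} > 1; pi_HCG = {pi_hcg} is below the product {product:.4f}"
            )
    else:
        raise ValueError(f"unknown scenario {scenario!r}; use one of {SCENARIOS}")

    probs = StageProbabilities(
        pi_soc=pi_soc, pi_fert=pi_fert, pi_hcg=pi_hcg, pi_clin=pi_clin, pi_lb=pi_lb
    )
    losses = None
    if pi_clin is not None and pi_lb is not None:
        losses = stage_losses(pi_hcg, pi_clin, pi_lb)
    return ScenarioResult(scenario=scenario, probabilities=probs, losses=losses)


@dataclass(frozen=True)
class StudyOutcome:
    """Per-study inputs to the bounds calculus.

    ``fec_hcg`` and ``pi_clin`` come from the fertile sub-cohort of a
    mixture fit (probability scale); ``pi_lb`` from published pregnancy
    outcome counts.
    """

    name: str
    fec_hcg: float
    pi_clin: float
    pi_lb: float

    @classmethod
    def from_fit(cls, name, fit, live_births, eligible_clinical_pregnancies):
        """Extract the fertile sub-cohort estimates from a mixture fit."""
        return cls(
            name=name,
            fec_hcg=fit.estimates.fec_hcg[0],
            pi_clin=fit.estimates.pi_clin[0],
            pi_lb=live_birth_probability(live_births, eligible_clinical_pregnancies),
        )


def summary_table(studies: Sequence[StudyOutcome]) -> pd.DataFrame:
    """Fecundabilities and chain probabilities per study (full precision)."""
    rows = []
    for s in studies:
        rows.append(
            {
                "study": s.name,
                "fec_hcg": s.fec_hcg,
                "fec_clin": s.fec_hcg * s.pi_clin,
                "pi_clin": s.pi_clin,
                "pi_lb": s.pi_lb,
                "loss_implantation_to_birth": 100.0 * (1.0 - s.pi_clin * s.pi_lb),
            }
        )
    return pd.DataFrame(rows)


def scenario_table(
    studies: Sequence[StudyOutcome],
    pi_soc: float,
    fixed: float = 0.9,
) -> pd.DataFrame:
    """The full scenario grid: one row per study x scenario.

    ``fixed`` is the value used by the ``pi_hcg_fixed`` and
    ``pi_fert_fixed`` scenarios.  Infeasible cells are kept as rows with
    NaN probabilities and the error message in ``note``; the remainder of
    the grid is still computed.
    """
    rows = []
    for s in studies:
        for scenario in SCENARIOS:
            fixed_value = None if scenario == "equal_fert_hcg" else fixed
            row = {
                "study": s.name,
                "scenario": scenario,
                "fert_hcg_product": s.fec_hcg / pi_soc,
                "pi_fert": math.nan,
                "pi_hcg": math.nan,
                "loss_before_implantation": math.nan,
                "loss_before_clinical": math.nan,
                "loss_before_live_birth": math.nan,
                "note": "",
            }
            try:
                res = decompose_under_scenario(
                    s.fec_hcg, pi_soc, scenario, fixed_value, pi_clin=s.pi_clin, pi_lb=s.pi_lb
                )
            except InfeasibleScenarioError as exc:
                row["note"] = f"infeasible: {exc}"
            else:
                row.update(
                    pi_fert=res.probabilities.pi_fert,
                    pi_hcg=res.probabilities.pi_hcg,
                    loss_before_implantation=res.losses.before_implantation,
                    loss_before_clinical=res.losses.before_clinical,
                    loss_before_live_birth=res.losses.before_live_birth,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def loss_before_live_birth_range(grid: pd.DataFrame) -> tuple[float, float]:
    """Min/max total loss over the studies x scenarios grid.

    This is the derived plausibility band for embryo and fetal mortality
    from fertilisation to birth (a summary of assumptions plus estimates,
    not a fitted quantity).
    """
    values = grid["loss_before_live_birth"].dropna()
    if values.empty:
        raise ValueError("grid has no feasible scenarios")
    return float(values.min()), float(values.max())
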