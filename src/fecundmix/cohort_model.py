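"""Deterministic forward model of a heterogeneous conception cohort.

The starting cohort is a finite mixture of one to three fertility
sub-cohorts.  Each sub-cohort ``c`` has a per-cycle probability of an
hCG-detectable conception (``FEC_HCG[c]``), and an hCG pregnancy becomes
clinically recognised with probability ``pi_CLIN`` (shared or per
sub-cohort).  Clinical fecundability is the product

    FEC_CLIN[c] = FEC_HCG[c] * pi_CLIN[c].

Cycle by cycle the model predicts expected pregnancy counts, removes the
predicted clinical pregnancies together with the *observed* finishers and
dropouts, and updates the mixture composition: because the fertile
sub-cohort conceives faster, the fertile fraction declines in successive
cycles, which is what bends the aggregate pregnancy-rate curve downward.
If a long follow-up horizon ``H`` is set, the expected number of women
never clinically pregnant after ``H`` cycles is

    NONPREG(H) = sum_c  n_initial * fraction[c] * (1 - FEC_CLIN[c])**H.

All probabilities live on the base-10 logit scale for estimation:
``theta = log10(p / (1 - p))``, ``p = 10**theta / (1 + 10**theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .study_data import StudyDataset

__all__ = [
    "logit10_to_prob",
    "prob_to_logit10",
    "stick_breaking_fractions",
    "fractions_to_stick_logits",
    "ParameterSet",
    "StudyDesign",
    "PredictionSeries",
    "ObservationPair",
    "predict_series",
    "observation_pairs",
]


def _check_finite(x: np.ndarray | float, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite, got {x!r}")


def logit10_to_prob(theta):
    """Inverse base-10 logit: ``10**theta / (1 + 10**theta)``.

    Accepts scalars or arrays; strictly increasing and symmetric,
    ``logit10_to_prob(-t) == 1 - logit10_to_prob(t)``.
    """
    arr = np.asarray(theta, dtype=float)
    _check_finite(arr, "logit")
    with np.errstate(over="ignore", invalid="ignore"):
        # np.where evaluates both branches; each is numerically safe on its own side
        out = np.where(arr >= 0, 1.0 / (1.0 + 10.0 ** (-arr)), 10.0**arr / (1.0 + 10.0**arr))
    return float(out) if np.isscalar(theta) or arr.ndim == 0 else out


def prob_to_logit10(p):
    """Base-10 logit ``log10(p / (1 - p))`` for ``p`` strictly inside (0, 1)."""
    arr = np.asarray(p, dtype=float)
    _check_finite(arr, "probability")
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"probability must lie strictly in (0, 1), got {p!r}")
    out = np.log10(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def stick_breaking_fractions(mixture_logits: Sequence[float], n_subcohorts: int) -> tuple[float, ...]:
    """Map ``n-1`` unconstrained base-10 logits to ``n`` mixture fractions.

    Fraction 1 is ``ilogit(l1)``; fraction 2 takes ``ilogit(l2)`` of the
    remaining stick, and the last fraction is the remainder, so the
    fractions always sum to 1.  With two sub-cohorts the single logit is
    exactly the logit of the fertile fraction ``%fert(1)``.
    """
    if len(mixture_logits) != n_subcohorts - 1:
        raise ValueError(
            f"{n_subcohorts} sub-cohorts need {n_subcohorts - 1} mixture logits, "
            f"got {len(mixture_logits)}"
        )
    remaining = 1.0
    fractions: list[float] = []
    for logit in mixture_logits:
        piece = remaining * logit10_to_prob(logit)
        fractions.append(piece)
        remaining -= piece
    fractions.append(remaining)
    return tuple(fractions)


def fractions_to_stick_logits(fractions: Sequence[float]) -> tuple[float, ...]:
    """Inverse of :func:`stick_breaking_fractions` (fractions must be positive)."""
    remaining = 1.0
    logits: list[float] = []
    for frac in fractions[:-1]:
        logits.append(prob_to_logit10(frac / remaining))
        remaining -= frac
    return tuple(logits)


@dataclass(frozen=True)
class ParameterSet:
    """Structural and residual parameters on their estimation scales.

    ``logit_fec_hcg``: base-10 logits of per-cycle hCG fecundability, one
    per sub-cohort, conventionally most fertile first.  ``logit_pi_clin``:
    length 1 (shared across sub-cohorts) or one per sub-cohort.
    ``mixture_logits``: ``n-1`` stick-breaking logits of the starting
    mixture (empty for a homogeneous cohort; for two sub-cohorts it is the
    logit of ``%fert(1)``).  ``log_sigma`` is the natural log of the
    residual scale and ``gamma`` the power-of-the-mean variance exponent.
    """

    logit_fec_hcg: tuple[float, ...]
    logit_pi_clin: tuple[float, ...]
    mixture_logits: tuple[float, ...] = ()
    log_sigma: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "logit_fec_hcg", tuple(float(v) for v in np.atleast_1d(self.logit_fec_hcg)))
        object.__setattr__(self, "logit_pi_clin", tuple(float(v) for v in np.atleast_1d(self.logit_pi_clin)))
        object.__setattr__(self, "mixture_logits", tuple(float(v) for v in np.atleast_1d(self.mixture_logits)))
        n = len(self.logit_fec_hcg)
        if n not in (1, 2, 3):
            raise ValueError(f"1-3 sub-cohorts supported, got {n}")
        if len(self.mixture_logits) != n - 1:
            raise ValueError(
                f"{n} sub-cohorts need {n - 1} mixture logits, got {len(self.mixture_logits)}"
            )
        if len(self.logit_pi_clin) not in (1, n):
            raise ValueError(
                f"pi_CLIN must be shared (length 1) or per sub-cohort (length {n}), "
                f"got length {len(self.logit_pi_clin)}"
            )

    @property
    def n_subcohorts(self) -> int:
        return len(self.logit_fec_hcg)

    @property
    def shared_pi_clin(self) -> bool:
        return len(self.logit_pi_clin) == 1

    @property
    def fractions(self) -> tuple[float, ...]:
        return stick_breaking_fractions(self.mixture_logits, self.n_subcohorts)

    @property
    def logit_fert1(self) -> float:
        """Base-10 logit of the fertile starting fraction (two sub-cohorts)."""
        if self.n_subcohorts != 2:
            raise ValueError("logit_fert1 is defined for the two-sub-cohort model only")
        return self.mixture_logits[0]

    @property
    def fec_hcg(self) -> tuple[float, ...]:
        return tuple(logit10_to_prob(t) for t in self.logit_fec_hcg)

    @property
    def pi_clin(self) -> tuple[float, ...]:
        probs = tuple(logit10_to_prob(t) for t in self.logit_pi_clin)
        return probs * self.n_subcohorts if len(probs) == 1 else probs

    @property
    def fec_clin(self) -> tuple[float, ...]:
        """Clinical fecundability per sub-cohort, FEC_HCG * pi_CLIN."""
        return tuple(f * p for f, p in zip(self.fec_hcg, self.pi_clin))

    @property
    def sigma(self) -> float:
        return math.exp(self.log_sigma)


@dataclass(frozen=True)
class StudyDesign:
    """Fixed quantities of one study the model conditions on.

    The starting cohort size and the per-cycle finisher/dropout counts are
    taken as data, not modelled; ``hcg_observed_cycles`` lists the cycles
    whose hCG counts were actually assayed; ``horizon`` switches on the
    long-run never-pregnant observation.
    """

    n_initial: float
    n_cycles: int
    observed_fin: tuple[float, ...]
    observed_drop: tuple[float, ...]
    hcg_observed_cycles: frozenset[int] = field(default=None)  # type: ignore[assignment]
    n_start_observed_cycles: frozenset[int] = field(default=None)  # type: ignore[assignment]
    horizon: int | None = None

    def __post_init__(self):
        if len(self.observed_fin) != self.n_cycles or len(self.observed_drop) != self.n_cycles:
            raise ValueError("observed_fin and observed_drop must have one entry per cycle")
        if self.hcg_observed_cycles is None:
            object.__setattr__(self, "hcg_observed_cycles", frozenset(range(1, self.n_cycles + 1)))
        else:
            object.__setattr__(self, "hcg_observed_cycles", frozenset(self.hcg_observed_cycles))
        if self.n_start_observed_cycles is None:
            object.__setattr__(self, "n_start_observed_cycles", frozenset(range(2, self.n_cycles + 1)))
        else:
            object.__setattr__(self, "n_start_observed_cycles", frozenset(self.n_start_observed_cycles))
        if self.horizon is not None and self.horizon < self.n_cycles:
            raise ValueError("horizon must be at least the number of reported cycles")

    @classmethod
    def from_dataset(cls, dataset: StudyDataset) -> "StudyDesign":
        horizon = dataset.nonpreg_horizon[0] if dataset.nonpreg_horizon else None
        return cls(
            n_initial=dataset.n_initial,
            n_cycles=dataset.n_cycles,
            observed_fin=tuple(r.finished for r in dataset.cycles),
            observed_drop=tuple(r.dropped for r in dataset.cycles),
            hcg_observed_cycles=dataset.hcg_observed_cycles,
            horizon=horizon,
        )


@dataclass(frozen=True)
class PredictionSeries:
    """Model-predicted cohort trajectory (real-valued expected counts).

    Arrays are indexed by cycle (row 0 = cycle 1); per-sub-cohort arrays
    have one column per sub-cohort, most fertile first.
    """

    n_pred: np.ndarray                  # (K,) women starting each cycle
    subcohort_sizes: np.ndarray         # (K, S)
    pct_fert: np.ndarray                # (K,) fraction of starters in sub-cohort 1
    preg_hcg_by_cohort: np.ndarray      # (K, S)
    preg_clin_by_cohort: np.ndarray     # (K, S)
    nonpreg_pred: float | None = None   # expected never-pregnant count at the horizon

    @property
    def preg_hcg_pred(self) -> np.ndarray:
        return self.preg_hcg_by_cohort.sum(axis=1)

    @property
    def preg_clin_pred(self) -> np.ndarray:
        return self.preg_clin_by_cohort.sum(axis=1)

    @property
    def nfert(self) -> np.ndarray:
        return self.subcohort_sizes[:, 0]

    @property
    def nsubf(self) -> np.ndarray:
        return self.subcohort_sizes[:, 1:].sum(axis=1)


def predict_series(params: ParameterSet, design: StudyDesign) -> PredictionSeries:
    """Run the cohort-depletion recursion and return the expected trajectory.

    Per cycle: split the starters into sub-cohorts by the current mixture,
    predict hCG and clinical pregnancies, deplete by *predicted* clinical
    pregnancies plus *observed* finishers and dropouts, and update the
    mixture (finishers/dropouts are assumed to leave the sub-cohorts
    proportionally).  Degenerate exhaustion (everyone pregnant or gone) is
    handled by freezing the mixture and flooring the cohort at zero.
    """
    S = params.n_subcohorts
    K = design.n_cycles
    fec_hcg = params.fec_hcg
    pi_clin = params.pi_clin
    fractions = list(params.fractions)

    n_pred = np.empty(K)
    sizes = np.empty((K, S))
    pct_fert = np.empty(K)
    hcg = np.empty((K, S))
    clin = np.empty((K, S))

    n = float(design.n_initial)
    frac = fractions[:]
    for k in range(K):
        n_pred[k] = n
        nc = [n * f for f in frac]
        hc = [nc[c] * fec_hcg[c] for c in range(S)]
        cc = [hc[c] * pi_clin[c] for c in range(S)]
        sizes[k] = nc
        pct_fert[k] = frac[0]
        hcg[k] = hc
        clin[k] = cc
        total_clin = sum(cc)
        survivors = n - total_clin
        if survivors > 1e-12:
            frac = [(nc[c] - cc[c]) / survivors for c in range(S)]
        n = max(n - total_clin - design.observed_fin[k] - design.observed_drop[k], 0.0)

    nonpreg = None
    if design.horizon is not None:
        fec_clin = params.fec_clin
        nonpreg = sum(
            design.n_initial * fractions[c] * (1.0 - fec_clin[c]) ** design.horizon
            for c in range(S)
        )

    return PredictionSeries(
        n_pred=n_pred,
        subcohort_sizes=sizes,
        pct_fert=pct_fert,
        preg_hcg_by_cohort=hcg,
        preg_clin_by_cohort=clin,
        nonpreg_pred=nonpreg,
    )


@dataclass(frozen=True)
class ObservationPair:
    """One (observed, predicted) pair entering the objective."""

    series: str                 # "n_start" | "preg_hcg" | "preg_clin" | "nonpreg"
    cycle_index: int | None
    observed: float
    predicted: float


def observation_pairs(dataset: StudyDataset, params: ParameterSet) -> list[ObservationPair]:
    """Assemble the observation vector for one study at given parameters.

    Order (deterministic, and the one the fit relies on):

    1. ``n_start`` for cycles 2..K — cycle 1 is fixed by design and is not
       an observation;
    2. ``preg_hcg`` for the cycles where hCG was assayed, ascending;
    3. ``preg_clin`` for cycles 1..K;
    4. the never-pregnant count at the horizon, when present.
    """
    design = StudyDesign.from_dataset(dataset)
    series = predict_series(params, design)
    pairs: list[ObservationPair] = []
    for rec in dataset.cycles[1:]:
        pairs.append(
            ObservationPair("n_start", rec.cycle_index, rec.n_start, series.n_pred[rec.cycle_index - 1])
        )
    for rec in dataset.cycles:
        if rec.preg_hcg is not None:
            pairs.append(
                ObservationPair(
                    "preg_hcg", rec.cycle_index, rec.preg_hcg, float(series.preg_hcg_pred[rec.cycle_index - 1])
                )
            )
    for rec in dataset.cycles:
        pairs.append(
            ObservationPair(
                "preg_clin", rec.cycle_index, rec.preg_clin, float(series.preg_clin_pred[rec.cycle_index - 1])
            )
        )
    if dataset.nonpreg_horizon is not None:
        pairs.append(ObservationPair("nonpreg", None, dataset.nonpreg_horizon[1], float(series.nonpreg_pred)))
    return pairs
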