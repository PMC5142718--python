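"""Seeded individual-level simulator of prospective conception studies.

Each simulated woman carries a latent sub-cohort label drawn from the
starting mixture.  Cycle by cycle she conceives an hCG-detectable
pregnancy with her sub-cohort's fecundability; a conception becomes
clinical with probability pi_CLIN, which removes her from the risk set at
the end of that cycle.  An hCG-only conception leaves her in the study
(cycles are independent given the label — no memory, no immunity).
Women still at risk at the end of a cycle withdraw independently with a
per-cycle dropout probability; survivors of the final reported cycle are
recorded as finishers.

If ``long_horizon`` is set, the never-pregnant count at the horizon is
ascertained from the *full latent cohort*: every woman's conception
process is simulated to the horizon regardless of dropout, mirroring the
deterministic model's long-run term which predicts the count from the
starting cohort with no dropout adjustment.  Dropout censors per-cycle
reporting only.

The deterministic companion :func:`expected_counts` wraps the forward
model's expected trajectory as a dataset, for zero-noise fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort_model import ParameterSet, StudyDesign, predict_series
from .study_data import CycleRecord, StudyDataset

__all__ = ["SimConfig", "SimTruth", "simulate_study", "expected_counts"]


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated study.

    ``params`` carries the generating mixture (fractions, per-sub-cohort
    hCG fecundability, pi_CLIN); its residual entries (sigma, gamma) are
    irrelevant to simulation, which is Bernoulli at the individual level.
    ``hcg_observed_cycles=None`` means hCG is assayed in every reported
    cycle.
    """

    n_initial: int
    params: ParameterSet
    n_cycles: int
    dropout_prob: float = 0.0
    long_horizon: int | None = None
    hcg_observed_cycles: frozenset[int] | None = None
    seed: int = 0
    study_name: str = "synthetic"

    def __post_init__(self):
        if self.n_initial < 1 or self.n_cycles < 1:
            raise ValueError("n_initial and n_cycles must be at least 1")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be a probability")
        if self.long_horizon is not None and self.long_horizon < self.n_cycles:
            raise ValueError("long_horizon must be at least n_cycles")
        if self.hcg_observed_cycles is not None:
            object.__setattr__(self, "hcg_observed_cycles", frozenset(self.hcg_observed_cycles))


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters and per-woman latent histories.

    ``first_clin_cycle[i]`` is the 1-based cycle of woman ``i``'s first
    clinical conception over the full latent horizon (0 = never);
    ``dropout_cycle[i]`` the cycle at whose end she withdrew (0 = never);
    ``hcg_conceptions`` the boolean conception matrix (woman x cycle) of
    hCG-detectable conceptions while she was still clinically unpregnant.
    """

    params: ParameterSet
    labels: np.ndarray
    first_clin_cycle: np.ndarray
    dropout_cycle: np.ndarray
    hcg_conceptions: np.ndarray


def simulate_study(config: SimConfig) -> tuple[StudyDataset, SimTruth]:
    """Simulate one study; same config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    p = config.params
    n = config.n_initial
    K = config.n_cycles
    H = config.long_horizon or K
    S = p.n_subcohorts

    labels = rng.choice(S, size=n, p=np.asarray(p.fractions))
    fec = np.asarray(p.fec_hcg)[labels]          # per-woman hCG fecundability
    pic = np.asarray(p.pi_clin)[labels]

    hcg_draw = rng.random((n, H)) < fec[:, None]
    clin_draw = rng.random((n, H)) < pic[:, None]
    drop_draw = rng.random((n, K)) < config.dropout_prob

    clin_event = hcg_draw & clin_draw            # clinical conception in that cycle
    # first clinical cycle over the full latent horizon (1-based, 0 = never)
    any_clin = clin_event.any(axis=1)
    first_clin = np.where(any_clin, clin_event.argmax(axis=1) + 1, 0)
    # latent conceptions after the first clinical one never happen
    alive = np.ones((n, H), dtype=bool)
    for cycle in range(1, H):
        alive[:, cycle] = alive[:, cycle - 1] & ~clin_event[:, cycle - 1]
    hcg_conceptions = hcg_draw & alive

    # reporting: dropout at the end of a cycle among women not clinically
    # pregnant in or before it
    dropout_cycle = np.zeros(n, dtype=int)
    at_risk = np.ones(n, dtype=bool)
    records: list[CycleRecord] = []
    observed = config.hcg_observed_cycles
    n_start_counts = []
    for cycle in range(1, K + 1):
        col = cycle - 1
        starters = at_risk
        n_start_counts.append(int(starters.sum()))
        hcg_count = int((starters & hcg_conceptions[:, col]).sum())
        clin_mask = starters & clin_event[:, col] & alive[:, col]
        clin_count = int(clin_mask.sum())
        still = starters & ~clin_mask
        drop_mask = still & drop_draw[:, col] & (dropout_cycle == 0)
        if cycle < K:
            dropped = int(drop_mask.sum())
            finished = 0
            dropout_cycle[drop_mask] = cycle
            at_risk = still & ~drop_mask
        else:
            # survivors of the last reported cycle finish; same-cycle
            # withdrawals are folded into the finisher count
            dropped = 0
            finished = int(still.sum())
            at_risk = np.zeros(n, dtype=bool)
        records.append(
            CycleRecord(
                cycle_index=cycle,
                n_start=n_start_counts[-1],
                preg_hcg=hcg_count if (observed is None or cycle in observed) else None,
                preg_clin=clin_count,
                finished=finished,
                dropped=dropped,
            )
        )

    horizon_meta = None
    if config.long_horizon is not None:
        never_pregnant = int((first_clin == 0).sum() + (first_clin > config.long_horizon).sum())
        horizon_meta = (config.long_horizon, float(never_pregnant))

    dataset = StudyDataset(
        study_name=config.study_name,
        n_initial=float(n),
        cycles=tuple(records),
        nonpreg_horizon=horizon_meta,
    )
    truth = SimTruth(
        params=p,
        labels=labels,
        first_clin_cycle=first_clin,
        dropout_cycle=dropout_cycle,
        hcg_conceptions=hcg_conceptions,
    )
    return dataset, truth


def expected_counts(
    params: ParameterSet,
    design: StudyDesign,
    rounding: str = "none",
    study_name: str = "expected",
) -> StudyDataset:
    """Deterministic dataset of expected counts from the forward model.

    ``rounding="none"`` keeps real-valued expectations (the dataset is
    flagged fractional; conservation holds exactly — test use only).
    ``rounding="nearest"`` rounds every count and repairs any conservation
    break by adjusting the finisher count, with a warning.
    """
    if rounding not in ("none", "nearest"):
        raise ValueError("rounding must be 'none' or 'nearest'")
    series = predict_series(params, design)
    K = design.n_cycles

    if rounding == "none":
        records = [
            CycleRecord(
                cycle_index=k + 1,
                n_start=float(series.n_pred[k]),
                preg_hcg=float(series.preg_hcg_pred[k]) if (k + 1) in design.hcg_observed_cycles else None,
                preg_clin=float(series.preg_clin_pred[k]),
                finished=float(design.observed_fin[k]),
                dropped=float(design.observed_drop[k]),
            )
            for k in range(K)
        ]
        horizon = (
            (design.horizon, float(series.nonpreg_pred)) if design.horizon is not None else None
        )
        return StudyDataset(
            study_name=study_name,
            n_initial=float(design.n_initial),
            cycles=tuple(records),
            nonpreg_horizon=horizon,
            allow_fractional=True,
        )

    # nearest-integer rounding with conservation repair
    n_start = [float(round(design.n_initial))]
    records = []
    repaired = False
    for k in range(K):
        clin = float(round(series.preg_clin_pred[k]))
        fin = float(round(design.observed_fin[k]))
        drop = float(round(design.observed_drop[k]))
        nxt = n_start[-1] - clin - fin - drop
        if nxt < 0:
            fin = max(fin + nxt, 0.0)
            nxt = n_start[-1] - clin - fin - drop
            repaired = True
        records.append(
            CycleRecord(
                cycle_index=k + 1,
                n_start=n_start[-1],
                preg_hcg=float(round(series.preg_hcg_pred[k]))
                if (k + 1) in design.hcg_observed_cycles
                else None,
                preg_clin=clin,
                finished=fin,
                dropped=drop,
            )
        )
        n_start.append(nxt)
    if repaired:
        warnings.warn(
            "integer rounding broke cohort conservation; finisher counts were adjusted",
            stacklevel=2,
        )
    horizon = (
        (design.horizon, float(round(series.nonpreg_pred))) if design.horizon is not None else None
    )
    return StudyDataset(
        study_name=study_name,
        n_initial=records[0].n_start,
        cycles=tuple(records),
        nonpreg_horizon=horizon,
    )
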