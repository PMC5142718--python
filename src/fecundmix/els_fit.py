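"""Extended-least-squares fitting of the mixture cohort-depletion model.

The objective is the extended least squares (ELS) criterion

    ELS = sum_i [ (y_i - f_i)**2 / g_i + ln g_i ],      g_i = sigma**2 * f_i**gamma,

i.e. a normal -2 log-likelihood (up to the data-independent ``n ln 2pi``
constant, which is omitted) with a power-of-the-mean residual variance.
``gamma = 0`` is homoscedastic; ``gamma = 2`` gives a constant residual
coefficient of variation.  ELS is minimised over the unconstrained
parameterisation (base-10 logits for probabilities, ``ln sigma``, free
``gamma``) by a quasi-Newton multistart, and the covariance of the
estimates is the inverse Hessian of ``ELS / 2`` at the optimum, so that
objective differences between nested fits are chi-square distributed.

Model variants (the nesting ladder used for hypothesis testing):

========  =====================================================================
Model 1   one sub-cohort (homogeneous fecundability)
Model 0   two sub-cohorts, shared pi_CLIN — the reference model
Model 00  Model 0 reparameterised: FEC_CLIN of the fertile sub-cohort is
          estimated directly and pi_CLIN derived as FEC_CLIN / FEC_HCG;
          statistically identical to Model 0 (same optimum objective)
Model 2   three sub-cohorts, shared pi_CLIN
Model 3   three sub-cohorts, per-sub-cohort pi_CLIN
Model 4   Model 0 with gamma fixed at 0
========  =====================================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.optimize
import scipy.stats
from statsmodels.tools.numdiff import approx_hess

from .cohort_model import (
    ObservationPair,
    ParameterSet,
    StudyDesign,
    fractions_to_stick_logits,
    logit10_to_prob,
    observation_pairs,
    predict_series,
    prob_to_logit10,
)
from .study_data import DataFormatError, StudyDataset, validate_dataset

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "FitOptions",
    "FitResult",
    "Interval",
    "OptimizationError",
    "els_objective",
    "fit_model",
    "parameter_intervals",
    "canonicalize_parameters",
    "embedded_parameters",
]


class OptimizationError(RuntimeError):
    """No start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class _Infeasible(Exception):
    """Raw vector maps outside the probability simplex (Model 00 only)."""

    def __init__(self, amount: float):
        self.amount = amount


@dataclass(frozen=True)
class ModelSpec:
    """Structural configuration of one model variant."""

    n_subcohorts: int = 2
    shared_pi_clin: bool = True
    gamma_fixed_zero: bool = False
    parameterization: str = "hcg+piclin"  # or "hcg+clin" (Model 00)

    def __post_init__(self):
        if self.n_subcohorts not in (1, 2, 3):
            raise ValueError("n_subcohorts must be 1, 2 or 3")
        if self.parameterization not in ("hcg+piclin", "hcg+clin"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return MODEL_NAMES[str(name)]
        except KeyError:
            raise ValueError(f"unknown model name {name!r}; use one of {sorted(MODEL_NAMES)}") from None

    @property
    def n_parameters(self) -> int:
        n = self.n_subcohorts
        count = (n - 1) + n                      # mixture logits + fecundabilities
        count += 1 if self.shared_pi_clin else n  # pi_CLIN (or the FEC_CLIN slot)
        count += 1                                # log sigma
        if not self.gamma_fixed_zero:
            count += 1
        return count


MODEL_NAMES: dict[str, ModelSpec] = {
    "0": ModelSpec(2, True, False, "hcg+piclin"),
    "00": ModelSpec(2, True, False, "hcg+clin"),
    "1": ModelSpec(1, True, False, "hcg+piclin"),
    "2": ModelSpec(3, True, False, "hcg+piclin"),
    "3": ModelSpec(3, False, False, "hcg+piclin"),
    "4": ModelSpec(2, True, True, "hcg+piclin"),
}


@dataclass(frozen=True)
class FitOptions:
    """Optimiser policy.

    Multistart: one start at neutral logits (all zeros, gamma 0), the rest
    jittered uniformly by +/- ``jitter`` on every free coordinate except
    ``log sigma``, which is always initialised at its closed-form profile
    optimum given the start's other values.  ``fixed_log_sigma`` /
    ``fixed_gamma`` remove those coordinates from estimation (test-only
    mode for zero-residual datasets, where both are unidentified).
    """

    n_starts: int = 8
    seed: int = 0
    jitter: float = 1.0
    gtol: float = 1e-8
    ftol: float = 1e-14
    maxiter: int = 1000
    prediction_floor: float = 1e-6
    fixed_log_sigma: float | None = None
    fixed_gamma: float | None = None


def els_objective(params: ParameterSet, pairs: Sequence[ObservationPair], *, prediction_floor: float = 1e-6) -> float:
    """ELS value for given parameters over an observation vector.

    Predictions are floored at ``prediction_floor`` inside the variance
    term so that near-zero expected counts in late cycles cannot collapse
    the variance.
    """
    if not pairs:
        raise ValueError("observation vector is empty")
    y = np.array([p.observed for p in pairs])
    f = np.array([p.predicted for p in pairs])
    return _els_value(y, f, params.sigma, params.gamma, prediction_floor)


def _els_value(y: np.ndarray, f: np.ndarray, sigma: float, gamma: float, floor: float) -> float:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    f_fl = np.maximum(f, floor)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        g = sigma**2 * f_fl**gamma
        if np.any(g <= 0) or not np.all(np.isfinite(g)):
            raise FloatingPointError("residual variance not positive and finite after flooring")
        value = float(np.sum((y - f) ** 2 / g + np.log(g)))
    if not math.isfinite(value):
        raise FloatingPointError("objective not finite")
    return value


# ---------------------------------------------------------------------------
# raw-vector parameterisation


def parameter_names(spec: ModelSpec, options: FitOptions | None = None) -> list[str]:
    """Names of the free coordinates, in vector order."""
    options = options or FitOptions()
    n = spec.n_subcohorts
    names: list[str] = []
    if n == 2:
        names.append("logit_fert1")
    elif n == 3:
        names += ["logit_frac1", "logit_frac2"]
    names += [f"logit_fec_hcg_{c + 1}" for c in range(n)]
    if spec.parameterization == "hcg+clin":
        names.append("logit_fec_clin_1")
    elif spec.shared_pi_clin:
        names.append("logit_pi_clin")
    else:
        names += [f"logit_pi_clin_{c + 1}" for c in range(n)]
    if options.fixed_log_sigma is None:
        names.append("log_sigma")
    if not spec.gamma_fixed_zero and options.fixed_gamma is None:
        names.append("gamma")
    return names


def _unpack(x: np.ndarray, spec: ModelSpec, options: FitOptions) -> ParameterSet:
    n = spec.n_subcohorts
    i = 0
    mixture = tuple(x[i : i + n - 1])
    i += n - 1
    fec_hcg = tuple(x[i : i + n])
    i += n
    if spec.parameterization == "hcg+clin":
        logit_fec_clin_1 = x[i]
        i += 1
        p_hcg = logit10_to_prob(fec_hcg[0])
        p_clin_fec = logit10_to_prob(logit_fec_clin_1)
        pi = p_clin_fec / p_hcg
        if pi >= 1.0:
            raise _Infeasible(pi - 1.0 + 1e-12)
        pi_clin = (prob_to_logit10(pi),)
    elif spec.shared_pi_clin:
        pi_clin = (x[i],)
        i += 1
    else:
        pi_clin = tuple(x[i : i + n])
        i += n
    if options.fixed_log_sigma is None:
        log_sigma = x[i]
        i += 1
    else:
        log_sigma = options.fixed_log_sigma
    if spec.gamma_fixed_zero:
        gamma = 0.0
    elif options.fixed_gamma is None:
        gamma = x[i]
        i += 1
    else:
        gamma = options.fixed_gamma
    return ParameterSet(
        logit_fec_hcg=fec_hcg,
        logit_pi_clin=pi_clin,
        mixture_logits=mixture,
        log_sigma=log_sigma,
        gamma=gamma,
    )


def _pack(params: ParameterSet, spec: ModelSpec, options: FitOptions) -> np.ndarray:
    if params.n_subcohorts != spec.n_subcohorts:
        raise ValueError(
            f"parameter set has {params.n_subcohorts} sub-cohorts, model expects {spec.n_subcohorts}"
        )
    x: list[float] = list(params.mixture_logits)
    x += list(params.logit_fec_hcg)
    if spec.parameterization == "hcg+clin":
        x.append(prob_to_logit10(params.fec_hcg[0] * params.pi_clin[0]))
    elif spec.shared_pi_clin:
        if len(set(params.logit_pi_clin)) != 1:
            raise ValueError("model has shared pi_CLIN but parameter set has distinct values")
        x.append(params.logit_pi_clin[0])
    else:
        pi = params.logit_pi_clin
        x += list(pi) if len(pi) == spec.n_subcohorts else [pi[0]] * spec.n_subcohorts
    if options.fixed_log_sigma is None:
        x.append(params.log_sigma)
    if not spec.gamma_fixed_zero and options.fixed_gamma is None:
        x.append(params.gamma)
    return np.array(x, dtype=float)


def canonicalize_parameters(params: ParameterSet) -> ParameterSet:
    """Order sub-cohorts by decreasing hCG fecundability (removes label switching)."""
    n = params.n_subcohorts
    if n == 1:
        return params
    order = sorted(range(n), key=lambda c: -params.logit_fec_hcg[c])
    if order == list(range(n)):
        return params
    fractions = params.fractions
    new_fracs = [fractions[c] for c in order]
    pi = params.logit_pi_clin
    return ParameterSet(
        logit_fec_hcg=tuple(params.logit_fec_hcg[c] for c in order),
        logit_pi_clin=pi if len(pi) == 1 else tuple(pi[c] for c in order),
        mixture_logits=fractions_to_stick_logits(new_fracs),
        log_sigma=params.log_sigma,
        gamma=params.gamma,
    )


def embedded_parameters(params: ParameterSet, to_spec: ModelSpec, *, split: float = 1e-3) -> ParameterSet:
    """Embed a fitted nested model into a richer variant's parameter space.

    Used to warm-start the alternative model of a likelihood-ratio test at
    a point whose objective exactly equals the null fit's: extra
    sub-cohorts are created by splitting the least fertile component into
    a ``1 - split`` / ``split`` pair with identical fecundability, and a
    shared pi_CLIN is replicated when the target estimates it per
    sub-cohort.  The embedding leaves every prediction unchanged.
    """
    fracs = list(params.fractions)
    fec = list(params.logit_fec_hcg)
    pi = list(params.logit_pi_clin)
    while len(fec) < to_spec.n_subcohorts:
        last = fracs.pop()
        fracs += [last * (1.0 - split), last * split]
        fec.append(fec[-1])
        if len(pi) > 1:
            pi.append(pi[-1])
    if not to_spec.shared_pi_clin and len(pi) == 1:
        pi = pi * to_spec.n_subcohorts
    gamma = 0.0 if to_spec.gamma_fixed_zero else params.gamma
    return ParameterSet(
        logit_fec_hcg=tuple(fec),
        logit_pi_clin=tuple(pi),
        mixture_logits=fractions_to_stick_logits(fracs),
        log_sigma=params.log_sigma,
        gamma=gamma,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class Convergence:
    status: str
    iterations: int
    gradient_norm: float
    best_start_index: int
    start_objectives: tuple[float, ...]
    algorithm: str = "L-BFGS-B"


@dataclass(frozen=True)
class Interval:
    point: float
    lower: float | None
    upper: float | None
    scale: str
    available: bool = True


@dataclass(frozen=True)
class FitResult:
    """One model variant fitted to one study."""

    model_spec: ModelSpec
    estimates: ParameterSet
    x: np.ndarray
    param_names: tuple[str, ...]
    standard_errors: dict[str, float] | None
    covariance: np.ndarray | None
    objective_value: float
    n_observations: int
    n_parameters: int
    convergence: Convergence
    pairs: tuple[ObservationPair, ...]
    options: FitOptions
    warnings: tuple[str, ...] = ()

    @property
    def degrees_of_freedom(self) -> int:
        return self.n_observations - self.n_parameters

    @property
    def residuals(self) -> np.ndarray:
        return np.array([p.observed - p.predicted for p in self.pairs])

    @property
    def observed_vector(self) -> np.ndarray:
        return np.array([p.observed for p in self.pairs])


def _prediction_vector(params: ParameterSet, design: StudyDesign, layout) -> np.ndarray:
    """Predictions in observation order; ``layout`` comes from :func:`_build_layout`."""
    series = predict_series(params, design)
    n_idx, hcg_idx, K, has_horizon = layout
    parts = [series.n_pred[n_idx], series.preg_hcg_pred[hcg_idx], series.preg_clin_pred]
    if has_horizon:
        parts.append(np.array([series.nonpreg_pred]))
    return np.concatenate(parts)


def _build_layout(dataset: StudyDataset, design: StudyDesign):
    n_idx = np.array([r.cycle_index - 1 for r in dataset.cycles[1:]], dtype=int)
    hcg_idx = np.array(
        [r.cycle_index - 1 for r in dataset.cycles if r.preg_hcg is not None], dtype=int
    )
    return n_idx, hcg_idx, design.n_cycles, dataset.nonpreg_horizon is not None


def _profile_log_sigma(y: np.ndarray, f: np.ndarray, gamma: float, floor: float) -> float:
    """Closed-form optimum of log sigma given everything else."""
    f_fl = np.maximum(f, floor)
    mean_sq = float(np.mean((y - f) ** 2 / f_fl**gamma))
    return 0.5 * math.log(max(mean_sq, 1e-30))


def fit_model(
    dataset: StudyDataset,
    spec: ModelSpec | str,
    options: FitOptions | None = None,
    extra_starts: Iterable[ParameterSet] = (),
) -> FitResult:
    """Minimise the ELS objective for one model variant on one study.

    Runs the seeded multistart described in :class:`FitOptions` plus any
    ``extra_starts`` (e.g. embeddings of a nested fit), keeps the best
    local optimum (ties break to the lowest start index), canonicalises
    the sub-cohort ordering, and derives standard errors from the inverse
    Hessian of half the objective.  A singular or indefinite Hessian
    yields ``standard_errors=None`` plus a warning flag rather than a
    failure.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    options = options or FitOptions()

    hard = [v for v in validate_dataset(dataset) if v.severity == "error"]
    if hard:
        raise DataFormatError(f"invalid dataset: {hard[0].message}")

    design = StudyDesign.from_dataset(dataset)
    layout = _build_layout(dataset, design)
    y_parts = [r.n_start for r in dataset.cycles[1:]]
    y_parts += [r.preg_hcg for r in dataset.cycles if r.preg_hcg is not None]
    y_parts += [r.preg_clin for r in dataset.cycles]
    if dataset.nonpreg_horizon is not None:
        y_parts.append(dataset.nonpreg_horizon[1])
    y = np.array(y_parts, dtype=float)
    n_obs = len(y)
    if n_obs <= spec.n_parameters:
        raise ValueError(
            f"{n_obs} observations cannot identify {spec.n_parameters} parameters"
        )

    floor = options.prediction_floor
    sigma_free = options.fixed_log_sigma is None
    names = parameter_names(spec, options)
    n_free = len(names)
    sigma_pos = names.index("log_sigma") if sigma_free else None

    def objective(x: np.ndarray) -> float:
        try:
            params = _unpack(x, spec, options)
            f = _prediction_vector(params, design, layout)
            return _els_value(y, f, params.sigma, params.gamma, floor)
        except _Infeasible as exc:
            return 1e10 + 1e12 * exc.amount
        except FloatingPointError:
            return 1e10

    def with_profiled_sigma(x: np.ndarray) -> np.ndarray:
        if not sigma_free:
            return x
        x = x.copy()
        try:
            params = _unpack(x, spec, options)
            f = _prediction_vector(params, design, layout)
            x[sigma_pos] = _profile_log_sigma(y, f, params.gamma, floor)
        except (_Infeasible, FloatingPointError):
            pass
        return x

    def repair(x: np.ndarray) -> np.ndarray:
        # Model 00 starts must satisfy FEC_CLIN < FEC_HCG of the fertile sub-cohort
        if spec.parameterization == "hcg+clin":
            i_clin = names.index("logit_fec_clin_1")
            i_hcg = names.index("logit_fec_hcg_1")
            if x[i_clin] >= x[i_hcg]:
                x = x.copy()
                x[i_clin] = x[i_hcg] - 0.5
        return x

    rng = np.random.default_rng(options.seed)
    starts: list[np.ndarray] = [with_profiled_sigma(repair(np.zeros(n_free)))]
    for _ in range(options.n_starts - 1):
        x = rng.uniform(-options.jitter, options.jitter, size=n_free)
        starts.append(with_profiled_sigma(repair(x)))
    for extra in extra_starts:
        starts.append(_pack(extra, spec, options))

    results = []
    for x0 in starts:
        try:
            res = scipy.optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                options={
                    "ftol": options.ftol,
                    "gtol": options.gtol,
                    "maxiter": options.maxiter,
                    "maxfun": 50 * options.maxiter,
                },
            )
            results.append(res)
        except Exception as exc:  # pragma: no cover - optimiser hard failure
            results.append(exc)

    objs = [r.fun if isinstance(r, scipy.optimize.OptimizeResult) else math.inf for r in results]
    if not np.any(np.isfinite(objs)) or min(objs) >= 1e9:
        raise OptimizationError("no start reached a feasible optimum", diagnostics=results)
    best_idx = int(np.argmin(objs))
    best = results[best_idx]

    warnings: list[str] = []
    est = canonicalize_parameters(_unpack(best.x, spec, options))
    x_canon = _pack(est, spec, options)
    obj_value = objective(x_canon)
    if obj_value > best.fun + 1e-9:  # canonical relabelling must not change the objective
        x_canon, obj_value = best.x, float(best.fun)
        est = _unpack(best.x, spec, options)
        warnings.append("canonical reordering skipped (objective changed)")

    se: dict[str, float] | None = None
    cov = None
    try:
        hessian = approx_hess(x_canon, lambda v: 0.5 * objective(v))
        eigvals = np.linalg.eigvalsh(hessian)
        if np.min(eigvals) <= 0:
            warnings.append("Hessian not positive definite; standard errors unavailable")
        else:
            cov = np.linalg.inv(hessian)
            se = {name: float(math.sqrt(cov[i, i])) for i, name in enumerate(names)}
    except (np.linalg.LinAlgError, FloatingPointError):
        warnings.append("Hessian evaluation failed; standard errors unavailable")

    pairs = tuple(observation_pairs(dataset, est))
    grad_norm = float(np.max(np.abs(best.jac))) if hasattr(best, "jac") else math.nan
    return FitResult(
        model_spec=spec,
        estimates=est,
        x=x_canon,
        param_names=tuple(names),
        standard_errors=se,
        covariance=cov,
        objective_value=float(obj_value),
        n_observations=n_obs,
        n_parameters=n_free,
        convergence=Convergence(
            status="converged" if best.success else str(best.message),
            iterations=int(best.nit),
            gradient_norm=grad_norm,
            best_start_index=best_idx,
            start_objectives=tuple(float(o) for o in objs),
        ),
        pairs=pairs,
        options=options,
        warnings=tuple(warnings),
    )


_Z_TABLE_LEVEL = 0.95


def parameter_intervals(fit: FitResult, level: float = 0.95) -> dict[str, Interval]:
    """Wald intervals on the natural scale of each parameter.

    Intervals are constructed on the estimation scale (logit / log) and
    the endpoints mapped through the inverse transform, so probability
    intervals respect (0, 1) by construction.  Quantile: the two-sided
    normal value (1.959964 at 95%).
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = float(scipy.stats.norm.ppf(0.5 + level / 2.0))
    out: dict[str, Interval] = {}
    for i, name in enumerate(fit.param_names):
        raw = float(fit.x[i])
        if name.startswith("logit_"):
            transform, scale = logit10_to_prob, "probability"
        elif name == "log_sigma":
            transform, scale = math.exp, "sigma"
        else:
            transform, scale = float, name
        point = transform(raw)
        if fit.standard_errors is None:
            out[name] = Interval(point, None, None, scale, available=False)
            continue
        se = fit.standard_errors[name]
        out[name] = Interval(point, transform(raw - z * se), transform(raw + z * se), scale)
    return out
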