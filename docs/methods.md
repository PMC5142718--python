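# Methods

## Model and assumptions

The unit of analysis is the menstrual cycle.  The starting cohort is a
finite mixture of one to three fertility classes; each class `c` has a
constant per-cycle probability `FEC_HCG[c]` of an hCG-detectable
conception, and a conception becomes clinically recognised with
probability `pi_CLIN` (shared across classes in the reference model).
Cycles are independent given the class label: there is no within-woman
decline, no covariates, and no continuous frailty — heterogeneity is
captured entirely by the discrete mixture.  Only a clinical pregnancy,
study completion or withdrawal removes a woman from the risk set; an
hCG-only (pre-clinically lost) pregnancy leaves her in, and she can
conceive again in later cycles.

The forward recursion predicts expected per-cycle counts, depleting the
cohort by *predicted* clinical pregnancies but *observed* finisher and
dropout counts, and updating the mixture composition under the
assumption that finishers and dropouts leave the classes
proportionally.  Consequently the predicted cohort size drifts from the
observed one wherever predicted and observed clinical counts differ,
and the observed cohort sizes of cycles 2..K are themselves fit
observations.  The observation vector for one study is, in order: the
cohort sizes N(2..K), the hCG counts of the assayed cycles, the
clinical counts of all cycles, and (where long-run follow-up exists)
the never-pregnant count at the horizon, predicted by the
geometric-survival term `sum_c N_c(1) (1 - FEC_CLIN[c])^H`.

## Estimation

All probabilities are estimated as base-10 logits; mixture fractions of
the three-class model use a stick-breaking construction (two
unconstrained logits), and fitted classes are relabelled in order of
decreasing fecundability to remove label switching.  The objective is
extended least squares, `sum_i [(y_i - f_i)^2/g_i + ln g_i]` with
`g_i = sigma^2 * max(f_i, 1e-6)^gamma`; the `n ln 2pi` constant is
omitted, which cancels from every model comparison.  The prediction
floor `1e-6` (women) prevents variance collapse when expected counts
approach zero in late cycles; estimates are insensitive to it because
floored cells carry near-zero residuals.

Minimisation uses L-BFGS-B with numerical gradients over the
unconstrained parameterisation, with a seeded 8-start policy: one start
at neutral logits (zero) and the rest jittered uniformly by ±1.
`log sigma` is always initialised at its closed-form profile optimum
given the other start values, because counts span three orders of
magnitude across designs and a unit-sigma start is arbitrarily far from
any optimum.  Ties between equally good starts break to the lowest
start index.  Standard errors are the square roots of the diagonal of
the inverse Hessian of half the objective (so that objective
differences behave as -2 log-likelihood ratios); an indefinite Hessian
yields absent standard errors plus a warning flag rather than an error.
Wald intervals are built on the estimation scale and mapped through the
inverse transform, so probability intervals respect (0, 1).

The reparameterised variant (Model 00) estimates the fertile class's
clinical fecundability directly and derives `pi_CLIN` as
`FEC_CLIN/FEC_HCG`; it is the same model, and cross warm starts between
the two forms make their optima agree to machine-level tolerance.
Raw-vector starts that would imply `pi_CLIN >= 1` are repaired before
optimisation and penalised during it.

Zero-residual (expected-count) datasets are used as fitting fixtures;
for them both `sigma` and `gamma` are fixed via test-only options,
because with all residuals zero the objective is unbounded below in
`log sigma` and linear in `gamma` — neither is identified.

## Hypothesis tests

Nested fits are compared by the difference of ELS values referred to a
chi-square with dof equal to the parameter-count difference.  The suite
(H1 one vs two classes, dof 2; H2 two vs three, dof 2; H3 shared vs
per-class clinical progression, dof 4; H4 homoscedastic vs free gamma,
dof 1) warm-starts every alternative at an exact embedding of its
fitted null (equal-fecundability split, vanishing third component,
replicated `pi_CLIN`), so test statistics are non-negative by
construction.  Differences in `[-1e-6, 0)` are treated as optimiser
noise and clipped; anything more negative raises a convergence-suspect
error instead of a silent wrong answer.

## Synthetic-data conditions

The simulator draws individual women: a latent class label from the
mixture, then per cycle a Bernoulli hCG conception and, if conceived, a
Bernoulli clinical conversion; clinical conception removes her at cycle
end.  Withdrawal is independent Bernoulli per cycle at rate 0.02 among
women still at risk — a round value of the same order as the real
cohorts' attrition, chosen once; the fit conditions on the realised
finisher/dropout counts, so results are insensitive to the exact rate.
Survivors of the last reported cycle are recorded as finishers.  The
long-horizon never-pregnant count is ascertained from the full latent
cohort (withdrawal censors per-cycle reporting only), matching the
model's long-run term, which predicts that count from the starting
cohort with no dropout adjustment.  Default study conditions for
simulation experiments mirror the 221-woman design: 9 reported cycles,
hCG assayed in all of them, 24-cycle horizon.

What the simulator does *not* emulate: staggered entry and per-cycle
finishing before the last cycle, reporting of first pregnancies only,
cycle-varying fecundability, or any dependence of withdrawal on
fertility.  Passing tests therefore show the pipeline is correct under
the model's own assumptions, not that those assumptions hold in any
real cohort.

## Problem sizes

Simulation-based checks use 20 replicates of 5000-woman studies for
parameter recovery, 40 replicates of 1000- and 2000-woman studies for
test size and power, and 10^5 simulated couples (100 seeded batches of
1000) for the forward-model/Monte-Carlo equivalence check — sizes at
which Monte-Carlo error is small against the tolerances while the full
suite stays inside a normal development loop.

## Known limitations

Two statistical caveats are properties of the method itself and are
deliberately reproduced, not corrected:

1. **Dependent observations.**  By the conservation identity, the
   cohort-size residuals are exact partial sums of the clinical-count
   residuals, yet ELS weights every observation as independent.  The
   information matrix is therefore overstated: in simulation at the
   two-class truth (5000 women, 20 replicates) the inverse-Hessian
   standard errors are roughly 2.5x smaller than the empirical sampling
   spread, and nominal 95% Wald intervals cover the truth for about 61%
   of parameter-replicate pairs.  Point estimates remain essentially
   unbiased (median probability-scale error 0.007).  A sandwich
   covariance would repair coverage but would depart from the
   inverse-Hessian convention this package reproduces.

2. **Boundary mixture test.**  H1 tests the absence of a mixture
   component; under the homogeneous null the mixing fraction is
   unidentified, and together with the dependent-observation
   pseudo-likelihood the naive chi-square(2) reference is
   anti-conservative: in simulation under a homogeneous truth
   (1000 women, 40 replicates) the nominal 5% test rejected 9/40 times,
   with null-fit optima verified by extended multistarts.  Observed H1
   statistics on two-class data are so large (chi-square 50-90 at
   n = 200-2000) that the qualitative conclusion is unaffected, but the
   printed p-values should be read as descriptive, not calibrated.

Other limitations: `pi_SOC` is an assumption, never estimated — the
library requires it explicitly and only the analysis scripts default it
to 0.80; the sub-fertile class's fecundability is weakly identified in
designs with few hCG-assayed cycles (its logit can run to the boundary
at realistic sample sizes, mirroring the large published standard
errors); and the scenario grid chains all quantities at full precision,
so isolated cells can differ by one unit in the last printed decimal
from tables produced with pre-rounded intermediates.
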