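# fecundmix

Mixture cohort-depletion models of human fecundability, and stage-wise
bounds on early embryo mortality, from prospective hCG-monitored
conception studies.

## The problem

Prospective time-to-pregnancy studies that assay human chorionic
gonadotrophin (hCG) daily can detect a conception about one week after
ovulation, when implantation begins.  In all three classic cohorts of
this kind (221, 200 and 518 women), per-cycle pregnancy rates decline
over successive cycles — the signature of a heterogeneous cohort in
which normally fertile couples conceive and leave the risk set early
while sub-fertile couples accumulate.  Estimates of fecundability (the
per-cycle probability of conception) computed from whole-cohort
aggregates are therefore biased downward, and so is every embryo-loss
estimate built on them.

`fecundmix` re-implements the analysis that resolves this: a discrete
two-sub-cohort mixture model of cohort depletion fitted to per-cycle
aggregate counts, likelihood-ratio comparison of nested variants, and a
conditional-probability calculus that converts the fertile-sub-cohort
estimates into plausible bounds on embryo mortality from fertilisation
to live birth.

## The model

The starting cohort of size N(1) is a two-point mixture: a fraction
%fert(1) of couples with per-cycle hCG fecundability FEC_HCG/FERT, the
rest with FEC_HCG/SUBF.  An hCG pregnancy progresses to clinical
recognition with probability π_CLIN (shared between sub-cohorts), so
clinical fecundability is FEC_CLIN = FEC_HCG × π_CLIN.  Cycle by cycle:

    NFERT(k)    = N(k) × %fert(k)
    PREG_HCG(k) = Σ_c N_c(k) × FEC_HCG,c
    PREG_CLIN(k)= Σ_c N_c(k) × FEC_HCG,c × π_CLIN
    N(k+1)      = N(k) − PREG_CLIN(k) − FIN(k) − DROP(k)
    %fert(k+1)  = (NFERT(k) − PREG_CLIN/FERT(k)) / (N(k) − PREG_CLIN(k))

where FIN and DROP are the observed finisher and dropout counts.  A
long-run follow-up term predicts the women never clinically pregnant
after H cycles as Σ_c N_c(1) × (1 − FEC_CLIN,c)^H.

Probabilities are estimated as base-10 logits.  The objective is
extended least squares,

    ELS = Σ_i [ (y_i − f_i)² / g_i + ln g_i ],   g_i = σ² f_i^γ,

a normal −2 log-likelihood with power-of-the-mean residual variance
(γ = 0 homoscedastic, γ = 2 constant CV), minimised by a seeded
quasi-Newton multistart; standard errors come from the inverse Hessian
of ELS/2.  Nested variants (one vs two vs three sub-cohorts, shared vs
per-sub-cohort π_CLIN, γ free vs zero) are compared by referring ELS
differences to a chi-square distribution.

Downstream, a live birth requires five stages, each with a conditional
success probability: sperm-ovum co-localisation (π_SOC), fertilisation
(π_FERT), implantation (π_HCG), clinical recognition (π_CLIN), live
birth (π_LB).  The fitted FEC_HCG identifies only the product
π_SOC·π_FERT·π_HCG, so pre-implantation loss (1 − π_HCG) is bounded by
scenario: assume π_SOC, then fix π_HCG = 0.9, set π_FERT = π_HCG, or
fix π_FERT = 0.9.

## Worked example

Generate a synthetic 221-woman study at the published estimates, fit
the mixture model and test homogeneity:

```python
from fecundmix import FitOptions, fit_model, likelihood_ratio_test, parameter_intervals
from fecundmix.els_fit import ModelSpec, embedded_parameters
from fecundmix.published import WILCOX
from fecundmix.synthetic_data import SimConfig, simulate_study

config = SimConfig(n_initial=221, params=WILCOX.parameter_set(), n_cycles=9,
                   dropout_prob=0.02, long_horizon=24, seed=1000)
dataset, _ = simulate_study(config)

fit = fit_model(dataset, "0", FitOptions(seed=1))
for name, iv in parameter_intervals(fit).items():
    print(f"{name:16s} {iv.point:7.3f} [{iv.lower:.3f}, {iv.upper:.3f}]")

null = fit_model(dataset, "1", FitOptions(seed=1))
alt = fit_model(dataset, "0", FitOptions(seed=1),
                extra_starts=[embedded_parameters(null.estimates, ModelSpec.from_name("0"))])
print(likelihood_ratio_test(null, alt))
```

prints

```
logit_fert1        0.690 [0.586, 0.779]
logit_fec_hcg_1    0.408 [0.372, 0.444]
logit_fec_hcg_2    0.110 [0.080, 0.148]
logit_pi_clin      0.797 [0.767, 0.823]
log_sigma          1.738 [0.586, 5.153]
gamma             -0.057 [-0.718, 0.604]
LRT: chi2 = 59.08, dof = 2, p = 1.48e-13
```

i.e. the fit recovers a ~69% fertile fraction with hCG fecundability
0.41 (fertile) vs 0.11 (sub-fertile) and clinical progression 0.80 —
close to the generating values 0.719 / 0.432 / 0.076 / 0.783 — and the
single-fecundability model is rejected decisively.

The full analysis is scripted:

```sh
python analysis/01_simulate_studies.py --seed 1   # synthetic study tables
python analysis/02_fit_mixture_models.py --seed 1 # mixture fits + intervals
python analysis/03_hypothesis_tests.py --seed 1   # four nested-model tests
python analysis/04_embryo_loss_bounds.py          # stage-wise loss grid
```

The last step chains the published fertile-sub-cohort estimates with
the live-birth outcome counts and prints, among others:

```
  study  fec_hcg  fec_clin  pi_clin  pi_lb  loss_implantation_to_birth
 wilcox    0.432     0.339    0.783  0.877                      31.274
zinaman    0.381     0.333    0.875  0.790                      30.877
   wang    0.462     0.349    0.755  0.871                      34.231

Total fertilisation-to-birth loss across studies and scenarios: 37.8% - 63.4%
```

so roughly a third of implanted embryos are lost before live birth, and
the total loss of fertilised eggs plausibly lies in the 40–60% band —
far below the 70–90% figures often quoted.

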