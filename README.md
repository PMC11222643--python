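# survrec

Counterfactual survival modelling and individualized adjuvant-chemotherapy
recommendation for registry-style breast-cancer cohorts, with debiased
evaluation of how much survival following those recommendations buys.

Adjuvant chemotherapy for triple-negative breast cancer is only partially
effective, and guideline rules (tumor > 1 cm or node-positive) ignore how
the benefit varies across patients.  `survrec` estimates that benefit per
patient from observational data: per-arm survival models predict each
patient's survival curve under chemotherapy, S1(t|x), and without it,
S0(t|x); the individual treatment effect is the difference in 10-year
restricted survival time,

    ITE_RST(x; τ) = ∫₀^τ S1(t|x) dt − ∫₀^τ S0(t|x) dt,      τ = 120 months,

and chemotherapy is recommended iff ITE_RST > 0.  Recommendation quality
is then measured by comparing patients whose actual treatment matched the
recommendation (Consis.) against those whose treatment contradicted it
(Inconsis.), with inverse-probability-of-treatment weighting (IPTW) to
remove baseline imbalance between the groups: hazard ratio, 10-year risk
difference, difference in 10-year restricted mean survival time, log-rank
tests and per-arm integrated Brier scores, each raw and IPTW-adjusted.

Four estimators share one fit/predict contract
(S_a(t|x) = exp(−H0_a(t)·e^{g_a(x)}) with Breslow baselines):

| kind | description |
|---|---|
| `t_cph` | T-learner, one linear Cox model per treatment arm |
| `t_deepsurv` | T-learner, one neural Cox model per arm |
| `bites` | shared encoder + two risk heads, Sinkhorn balancing penalty |
| `snb` | same two-head architecture with self-normalizing (SELU) layers |

The balanced variants add α · S_ε(Φ(x)|a=0, Φ(x)|a=1) to the training
loss, a debiased entropic-optimal-transport (Sinkhorn) divergence that
pulls the two arms' latent representations together and counteracts
treatment-assignment bias.

Since the motivating registry data are access-restricted, the package
ships a first-class synthetic cohort generator with registry-like
marginals, confounded treatment assignment (older / smaller-tumor
patients treated less), proportional-hazards outcomes whose treatment
benefit grows with age, tumor size and node count, staggered
administrative censoring — and exact ground truth (true propensities,
per-arm hazards and closed-form true ITEs) against which every stage is
tested.  Interpretation layers regress ITEs on covariates with a
region random intercept, and decompose the consistency effect into
interventional direct/indirect (INDE/INIE) parts with the received
treatments as mediators.

## Worked example

```python
from survrec import CohortConfig, ExperimentConfig, NetConfig, run_experiment

config = ExperimentConfig(
    cohort=CohortConfig(n=10_000, seed=1),
    models=("t_cph", "snb"),
    net_config=NetConfig(shared_layers=(32, 16), head_layers=(16,),
                         alpha=1.0, lr=3e-3, max_iter=3000, patience=1000),
    n_boot=50, seed=1, out_dir="run1")
results = run_experiment(config)
```

or, equivalently, `survrec run-all --models t_cph,snb --seed 1 --out-dir run1`.
The pipeline simulates the cohort, holds out the earliest diagnosis year
as a concealed external test set, splits the remainder 70/30, fits the
models on the training set, and evaluates the recommendations.  Printing
the effect reports of this exact run gives:

```
t_cph/test:     HR=0.74 (0.60-0.91)  IPTW-HR=0.64  IPTW-RD=8.95%   IPTW-DRMST=9.01 mo  IBS=(0.143, 0.128)
t_cph/external: HR=0.67 (0.52-0.85)  IPTW-HR=0.62  IPTW-RD=11.63%  IPTW-DRMST=8.25 mo  IBS=(0.154, 0.131)
snb/test:       HR=0.86 (0.69-1.06)  IPTW-HR=0.81  IPTW-RD=6.81%   IPTW-DRMST=3.83 mo  IBS=(0.145, 0.129)
snb/external:   HR=0.75 (0.59-0.96)  IPTW-HR=0.69  IPTW-RD=8.00%   IPTW-DRMST=5.82 mo  IBS=(0.153, 0.133)
```

Both recommenders are protective: patients treated in accordance with the
model recommendation have, after IPTW debiasing, roughly 0.6–0.8 times
the death hazard of patients treated against it, an 7–12 percentage-point
lower 10-year mortality, and 4–9 more months of 10-year restricted
survival time.  (On this generator the outcome model is log-linear, so
the linear T-learner is well-specified and hard to beat; the balanced
networks' advantage is robustness of the latent representation under
treatment imbalance, which the test suite checks directly.)  The
interpretation layer on the combined test populations prints

```
covariate                        beta  95% CI
age                             0.406  (0.391, 0.421)
tumor_size_mm                   0.247  (0.235, 0.258)
positive_nodes                  0.088  (0.019, 0.157)
upper_inner                   -11.982  (-12.529, -11.435)
INDE=-0.053 (-0.093, -0.023)  INIE=-0.004 (-0.013, 0.004)
```

— each extra millimetre of tumor adds ~0.25 months of predicted 10-year
benefit from chemotherapy, benefit rises with age and node count and
drops for upper-inner-quadrant tumors (all matching the generator's
built-in interaction signs), and the mediation decomposition attributes
the mortality reduction of recommendation-consistency to a direct path
(INDE < 0) rather than to the treatment mix (INIE ≈ 0).

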