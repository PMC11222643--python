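# Methods

## Problem and estimand

For a patient with baseline covariates x (demographics and tumor
characteristics at diagnosis), let S1(t|x) and S0(t|x) be the survival
functions under adjuvant chemotherapy and under no chemotherapy.  The
package's estimand is the individual treatment effect on the
restricted-survival-time (RST) scale,

    ITE_RST(x; tau) = ∫0^tau S1(t|x) dt − ∫0^tau S0(t|x) dt,

in months of expected survival gained within the horizon tau = 120 months
(10 years).  A patient is recommended chemotherapy iff ITE_RST > 0; an
exact zero recommends no chemotherapy (a conservative, avoid-overtreatment
tie-break — ties have measure zero for continuous predictors, so the
choice is inconsequential in practice but is configurable).

Only one potential outcome is observed per patient, so both curves are
predictions from counterfactual survival models.

## Risk models

All four estimators share one contract: per-arm log-risk functions
g_a(x) and treatment-specific Breslow baseline cumulative hazards
H0_a(t), combined as S_a(t|x) = exp(−H0_a(t)·exp(g_a(x))) — conditional
proportional hazards within each arm, with no time-varying effects.
Every model minimizes the same negative log Cox partial likelihood with
the Breslow tie convention (ties are rare at month resolution; Breslow
matches the Breslow baseline estimator and is the usual neural-Cox
choice).

* **t_cph** — T-learner: one linear Cox model per treatment arm
  (lifelines), reference-dropped one-hot design.  Zero-variance columns
  get coefficient 0.
* **t_deepsurv** — T-learner with one feed-forward ReLU network per arm
  trained by Adam on the partial likelihood, with an internal validation
  split and early stopping.
* **bites** — end-to-end two-head network: shared encoder Φ(x), two
  arm-specific risk heads g_a(Φ(x)); total loss is the sum of per-arm
  partial likelihoods plus α times a debiased Sinkhorn divergence between
  the arms' latent clouds.  The divergence enters the loss as a penalty
  to be *minimized*: balancing means pulling the two arms' latent
  distributions together, so minimization is the only direction
  consistent with its purpose.
* **snb** — the same architecture with self-normalizing layers: SELU
  activations, LeCun-normal initialization and alpha dropout, whose
  fixed point keeps activations near zero mean / unit variance on
  standardized inputs (verified at initialization by a test on an
  8-layer stack).  Empty `shared_layers` yields an identity encoder —
  the direct two-head analogue of the T-learner, used as an ablation.

The neural substrate is a small numpy feed-forward framework with
hand-written backprop and Adam; at the cohort sizes this package targets
(10^3–10^4 patients, tens of features), dense numpy passes train a model
in seconds on one CPU, and the closed-form Cox and Sinkhorn gradients
are each verified against finite differences.

Training details: mini-batches (default 256) are stratified by arm so
both heads receive gradient every step; an arm with no events in a batch
contributes no Cox term that step.  Early stopping monitors the
validation Cox loss every optimizer step and stops after `patience`
(default 1,000) steps without improvement, restoring the best
parameters.  Hyperparameter tuning evaluates a (optionally subsampled)
grid by mean validation loss over the five training folds, breaking ties
toward the smaller network and lower α.

### Sinkhorn divergence

S_eps(A,B) = OT_eps(A,B) − ½OT_eps(A,A) − ½OT_eps(B,B) with
squared-Euclidean cost, uniform weights, and log-domain Sinkhorn
iterations (default eps = 0.1 on standardized latents, 20 iterations
during training, 200 for standalone evaluation).  Gradients with respect
to the points use the converged transport plan (envelope theorem), the
standard fixed-plan approximation for Sinkhorn training losses.  The
debiased form is symmetric, nonnegative and zero iff the clouds
coincide.

## Synthetic cohort generator

The generator emulates a registry cohort of triple-negative breast
cancer patients; it is the package's test bed, providing the ground
truth the real registry cannot.

* **Covariates**: age ~ N(58, 13²) years (clipped 25–92); tumor size
  lognormal with median 21 mm and IQR ≈ 13–32; positive nodes
  zero-inflated (62% node-negative, geometric with mean 4 among
  positives); grade 1–4 with ~82% G3; 6 tumor locations, 3 histologies,
  laterality, race, marriage, income with registry-like frequencies; 18
  reporting regions; diagnosis years 2010–2016 with ~15% in the first
  year (which serves as the concealed external cohort).
* **Treatment**: Bernoulli in a logistic propensity — older patients and
  smaller tumors are treated less, node-positive and high-grade disease
  more; the intercept is calibrated so ~85% receive chemotherapy.  This
  reproduces the strong observed confounding (unweighted |SMD| between
  arms up to ~1 for age).
* **Outcomes**: exponential proportional hazards per arm by default
  (Weibull shape option available).  The untreated log-hazard rises with
  age, size, nodes and grade; the treated/untreated log hazard ratio is
  θ(x) = θ0 + interactions, with protective (negative) interactions for
  age, size and node count and a harmful interaction for
  upper-inner-quadrant location.  Under these defaults ~84% of patients
  truly benefit (positive ITE) and ~16% are harmed — the heterogeneity
  the recommenders must find.  The exponential choice gives closed-form
  true RST, (1−exp(−λτ))/λ, so oracle tests need no numerical
  integration; the Weibull branch uses 200-point Gauss–Legendre
  quadrature (relative error far below 1e-6).
* **Censoring**: staggered administrative censoring (later diagnosis
  years have shorter maximum follow-up, as with a fixed registry cutoff;
  132 months for the first year) plus independent exponential censoring
  (0.007/month), calibrated jointly with the baseline rate
  (0.0025/month) to ~19% observed mortality and ~60 months median
  follow-up.

What the generator does **not** emulate: joint covariate dependence
beyond the propensity model (covariates are drawn independently),
competing causes of death, measurement error, informative censoring, or
calendar-time trends in treatment practice.  Tests passing on this
generator therefore demonstrate the pipeline's correctness and its
behavior under known confounding — not performance on real registry
data.

Sign convention: `interaction_coefs` act on the log hazard ratio, so a
*negative* coefficient means benefit increases with the covariate; the
monotonicity property (ITE nondecreasing in age/size/nodes) is asserted
under protective interactions.

## Preprocessing

Binary categoricals become one 0/1 column; categoricals with ≥3 levels
are one-hot encoded — full dummies for the neural models,
reference-level dropped for linear/propensity models (a full dummy block
is singular in a linear fit).  Grade is encoded against its fixed 1–4
codebook (rare G4 may be absent from a training split); truly unknown
levels raise an error naming the column.  Continuous covariates are
standardized (sample SD) with statistics from the fitting rows only —
required for stable neural training and for the self-normalizing input
assumption; whether to standardize at all was an open design point,
resolved in favor of standardizing.  The split carves out the
external-year cohort first, splits the remainder 70/30 stratified
jointly by treatment and event (stabilizes small synthetic runs), and
partitions the training set into five folds.

## Recommendation evaluation

Patients are partitioned into recommendation-consistent (Consis.) and
-inconsistent (Inconsis.) groups by comparing the recommendation with
the treatment actually received.  Because membership is not randomized,
comparisons are debiased by IPTW: a main-effects logistic model of
membership on the adjusted baseline covariates (age, tumor size, node
count, grade, histology, location, laterality, race, marriage, income —
treatment variables are post-exposure and excluded), stabilized weights
w = P(G=g)/P(G=g|X), truncated at the 1st/99th weight percentiles
(stabilization and truncation are standard variance-control choices the
source design left open).  TNM stage is a deterministic function of
tumor size and node count in the synthetic cohort and is therefore not
added as a separate adjusted covariate.

Metrics, each raw and IPTW-weighted:

* **HR** — Cox model of the group effect; the raw ("multivariate") form
  adjusts for the covariate list above (with a light ridge, 0.01, since
  rare dummy levels at desk-scale n otherwise break Newton–Raphson); the
  IPTW form is the weighted univariate group fit with robust sandwich
  variance ("IPTW-adjusted" is read as weight-based, not doubly
  adjusted).
* **RD** — difference in 10-year event probability from (weighted)
  Kaplan–Meier: 100·[(1−S_Inconsis(τ)) − (1−S_Consis(τ))]; positive
  means following recommendations is protective.
* **DRMST** — difference in area under the (weighted) KM curves to τ,
  Consis. − Inconsis., in months.
* **log-rank** — standard test; the weighted variant plugs IPTW weights
  into the at-risk and event sums.
* **IBS** — integrated Brier score of the underlying model's curves
  against factual outcomes within each treatment arm, with
  inverse-probability-of-censoring weights from the censoring KM;
  integration stops (with a warning) where the censoring survival hits
  zero.  Counterfactual IBS is unobservable and computed only against
  generator truth.

CIs: analytic (robust) for HRs; percentile bootstrap (default 200
patient-level replicates, propensity refit in every replicate) for RD
and DRMST.  A replicate that loses one group entirely is skipped.  An
evaluation where one consistency group is empty returns a flagged
degenerate report rather than an error.

The guideline comparator recommends chemotherapy for node-positive
disease or node-negative T1–T3 tumors larger than 10 mm; T stage is
derived from tumor size (≤20 / ≤50 / >50 mm) and N stage from node
count (0 / 1–3 / 4–9 / ≥10), and stages outside the quoted rule fall
back to the node-positivity criterion.

## Interpretation layers

* **Insight regression** — linear mixed model (REML) of per-patient ITEs
  on covariates in natural units (years, mm, node count, 0/1
  indicators), random intercept per reporting region.  A beta of 0.05
  for tumor size reads: each additional millimetre raises the predicted
  10-year survival-time benefit of chemotherapy by 0.05 months.  A
  single-region cohort falls back to OLS with a warning.
* **Mediation** — linear-specification interventional decomposition of
  the consistency effect with the received treatments as mediators:
  INDE is the exposure coefficient in the outcome model given mediators;
  INIE is the product-of-coefficients sum; in the all-linear case
  INDE + INIE equals the total-effect slope exactly (identity tested to
  1e-6).  The outcome is the 10-year death indicator on a
  linear-probability scale (the event-by-τ flag; censored-before-τ
  patients count as non-events — a documented simplification of the
  slope presentation).  The precise estimator behind the interventional
  effects was not pinned down by the source design; the linear
  product-of-coefficients reading is the package's documented choice.

## Problem sizes and numerical choices

Default experiment sizes are chosen for single-CPU runs: cohorts of
2,000–10,000; networks of one or two hidden layers (8–32 units);
Sinkhorn eps 0.1 / 20 iterations in training; monthly survival grid
0–120; trapezoidal RST integration (error < 0.05 months vs the closed
form on exponential curves); bootstrap 200 replicates.  Determinism:
every stochastic component takes a seed, and identical configs produce
bit-identical cohorts, training trajectories and ITE tables.

## Known limitations

* Per-arm conditional PH with a single scalar log-risk: no time-varying
  or non-proportional effects.
* The propensity model for consistency-group membership is main-effects
  logistic; when membership is a deterministic threshold function of
  covariates (as with any deterministic recommender), that model is
  misspecified and residual imbalance above the 0.1 criterion can
  remain — the balance guarantee holds when membership truly follows a
  log-odds model.
* With ~15% untreated, the minority-arm Cox fit at n ≈ 5,000 has only
  ~160 events for ~20 features; per-arm estimates of *interaction*
  signals are variance-limited at that scale, which is precisely the
  imbalance-robustness argument for the balanced two-head architectures.
* Mixture-of-risk-groups models and time-dependent Shapley attributions
  are out of scope, as are competing-risks endpoints.
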