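# Methods

## Outcome model

The observed data per subject are (X, δ, Z, G₁, G₂): follow-up time,
event indicator, pre-immune indicator and the genotype dummies of one
bi-allelic marker (G₁ the allele count, G₂ the heterozygote indicator;
together they span dominant, additive, recessive and overdominant
effects). A pre-immune subject is stored as (X=0, δ=1, Z=1); all
survival-part computations condition on Z=0. Times are continuous and
unit-agnostic — every statistic in the package is invariant to a common
positive rescaling of the times (verified by test).

The two-part distribution is

* **zero part** — P(Z=1 | G₁) = expit(θ + βG₁), a logistic model in the
  allele count;
* **continuous part** — for Z=0, an improper survival function derived
  from a first-activation scheme: a latent number K of activated B-cell
  clones, each with an independent Gamma(1, τ) affinity U, and clone-level
  survival A₀(t)^U with A₀(t) = exp{−H₀(t)}. The subject's event time is
  the minimum over clones; K = 0 means the event never occurs.

With K in the Katz family — recurrence Pr(x+1) = Pr(x)(ω + γx)/(1+x),
ω > 0, γ < 1; Poisson at γ = 0, negative binomial for 0 < γ < 1,
under-dispersed (binomial-type) for γ < 0 — the marginal survival is the
Katz probability generating function evaluated at the Laplace transform
of the affinity law. Genotype shifts the affinity scale multiplicatively
(τ → τ·e^{α₁G₁+α₂G₂}) and the clone-count dispersion additively
(γ = γ₁G₁ + γ₂G₂), giving the closed forms implemented in
`twistest.model`. The tail defect (probability of zero clones) is
(1 − γG)^{ω/γG}, continuously extended to e^{−ω} at γG = 0.

Assumptions worth keeping in mind: proportional (multiplicative) genotype
effects on the clone-level hazard; independent, non-informative
censoring; and a follow-up long enough that essentially every
immune-reactive subject fails within it — the last assumption is what
makes the terminal Nelson–Aalen value a sensible plug-in for ω.

## Parameters

| parameter | meaning | default |
|---|---|---|
| θ | logistic intercept; expit(θ) is the reference pre-immune rate | logit(0.1) |
| β | log odds-ratio of pre-immunity per minor allele | 0 |
| ω | mean clone count, reference group; tail defect e^{−ω} | ln 2 (tail 0.5) |
| τ | affinity scale (Gamma(1, τ)) | 1 |
| α₁, α₂ | log affinity-scale effects of G₁, G₂ | 0 |
| γ₁, γ₂ | dispersion effects of G₁, G₂ (γG < 1 required) | 0 |
| H₀(t) | baseline integrated hazard | identity |

`ModelParams` validates ω, τ > 0 and the Katz constraint γ₁G₁ + γ₂G₂ < 1
for every observable genotype at construction.

## The statistic

Both parts are score tests computed under the pooled null, so no
alternative-model fitting is ever required.

* **S₁** (1 df): score V = Σ G₁ᵢ(Zᵢ − π̂₀) with π̂₀ the observed
  pre-immune proportion; information J = π̂₀(1−π̂₀)·Σ(G₁ᵢ−Ḡ₁)², i.e. the
  efficient information with the intercept profiled out (centring G₁ is
  what profiling contributes; the score itself is unchanged because the
  residuals sum to zero).
* **S₂** (4 df): components Û_a = Σ δᵢ W_a(tᵢ){g_aᵢ − ḡ_a(tᵢ)} over the
  Z=0 sample, a = (α₁, α₂, γ₁, γ₂) paired with covariates (G₁, G₂, G₁, G₂)
  and weights (W₁, W₁, W₂, W₂). The weights come from the hazard-scale
  expansion of the model around the null: the α-direction perturbs the
  log-hazard by W₁(t)·g and the γ-direction by W₂(t)·g, with
  W₁ = 1 − 2Λ(t)/ω and W₂ = 1 − Λ(t)/ω. Plug-ins: the left-continuous
  Nelson–Aalen path for Λ(t⁻), its terminal (right-continuous) value at
  the last failure for ω̂. The information is the martingale covariance
  of a weighted logrank score, Î_ab = Σ δᵢ W_a(tᵢ)W_b(tᵢ)·Ĉ_ab(tᵢ) with
  Ĉ the at-risk covariance of the covariate pair. Equivalently, S₂ is the
  score test at zero of a Cox partial likelihood in the *time-varying*
  covariates W_a(t)·g_a; the test suite exploits this by comparing Î to
  the numerically differentiated observed information of that partial
  likelihood (relative agreement 1e−4) and Û to its gradient. With unit
  weights the construction collapses onto the classical logrank score,
  cross-checked against lifelines.

S = S₁ + S₂ is referred to χ² with 1 + rank(Î) degrees of freedom.
Rank deficiency (monomorphic variant, no heterozygotes) is handled by an
eigenvalue-thresholded pseudo-inverse (relative tolerance 1e−10) with the
df reduced to the rank and a `rank-deficient-information` flag; a
degenerate logistic part (π̂₀ ∈ {0,1} or constant G₁) sets S₁ = 0, drops
its df and flags `degenerate-logistic-part`. This behaviour is a design
choice aimed at screening robustness: a test that errors on monomorphic
columns is useless on real genotype matrices.

## The comparator (TLRT)

A two-part logrank test in the Lachenbruch style for semi-continuous
outcomes: part 1 is the score test of equal pre-immune proportions across
the genotype groups under the pooled null (genotype categorical, 2 df —
algebraically the Pearson chi-square of the 2×3 table), part 2 the
k-sample logrank (k = 3, 2 df) on Z=0 subjects, implemented as the
unit-weight special case of the S₂ machinery restricted to
group-indicator covariates. Parts and dfs add (χ²₄ with all three groups
present). A 1-df (additive-coded) binary part would be a defensible
alternative; the categorical form was chosen for symmetry with the
k-sample survival part.

## The generator

`Scenario` defaults are the study conditions: n = 1000 subjects,
1000 replications, MAF 0.2, 10% reference pre-immune rate, tail defect
0.5 (ω = ln 2), τ = 1, H₀(t) = t, no censoring, level 0.05. Genotypes
are sums of two Bernoulli(MAF) draws; pre-immune status follows the
logistic part; event times invert the closed-form survival functions
analytically (uniform draws at or below the genotype's tail defect map to
infinity). Effect sizes are specified as risk ratios e^α, e^β and a
dispersion shift γ₁, translated to (α₁, α₂), (γ₁, γ₂) by the genetic
model (e.g. additive: α₁ = ½·log risk, α₂ = 0).

Two mechanisms the closed forms do not dictate had to be decided:

* **Tolerant subjects without censoring** are administratively censored
  one time unit past the largest finite event time of the replicate.
  This keeps them at risk through the last failure, which is required
  for ω̂ = Λ̂(t_max) to estimate ω (relative bias < 2% at n = 10⁴,
  verified by test). Any rule that censors them earlier biases ω̂ down.
* **Censoring calibration**: the uniform bound c solves
  E[min(T, c)]/c = target on a fixed-seed Monte-Carlo sample of 10⁵
  finite event times (root-finding by Brent), so the censored percentage
  refers to immune-reactive subjects only — the tolerant fraction is
  excluded from the target by construction. Under censoring, tolerant
  subjects receive the same U(0, c) censoring time as everyone else.
  The calibration stream is independent of replicate streams, so power
  runs cannot perturb it.

Each replicate uses its own generator seeded `seed + replicate index`;
fixing the scenario seed fixes every byte of the output (verified by
test).

What the generator emulates: genotype-dependent mixing of the three
subject classes, improper event-time laws, uniform independent
censoring. What it does not: linkage disequilibrium between variants
(screening nulls are drawn independently), covariates other than the
variant, informative censoring, interval-censored ADA detection (real
titers are assessed at visits, not continuously), or genotyping error.
Passing tests therefore validate the statistic's operating
characteristics under the stated mechanism, not robustness to these
real-data features.

## Numerical choices

* |γG| < 1e−8 routes through the Poisson (γ → 0) closed form to avoid
  0/0 in the Katz exponent; continuity at the boundary is tested at
  ±1e−8.
* Breslow tie handling throughout (increment d/Y at a tied failure
  time); the left-continuous Λ̂(t⁻) excludes all jumps at t itself.
* Λ̂/ω̂ is clipped to [0, 1] against floating-point overshoot so
  W₁ ∈ [−1, 1] and W₂ ∈ [0, 1] hold exactly.
* Survival inversion clips negative round-off at u = 1 to t = 0; the
  round-trip S(invert(u)) = u is exact to 1e−10 (tested on 1000 random
  parameter draws).
* The latent-clone sampler covers γG ≥ 0 only (Poisson / negative
  binomial); the under-dispersed Katz branch is a binomial-type law that
  is ill-defined for non-integer ω/|γ|, so sampling there uses the
  analytic inverse instead. The sampler exists purely as a mechanism-level
  cross-check of the closed forms (two-sample KS at n = 10⁵).

## Power-study scale

The bundled acceptance checks run each power cell at the full published
scale (1000 replications of n = 1000); a cell takes a few seconds thanks
to vectorised scoring, and the whole acceptance module runs in well under
a minute. The `power-study` CLI accepts `--replications` to scale any
grid down for smoke runs.

## Known limitations

* The weights (W₁, W₂) are tuned to the mechanistic alternatives; the
  equal-weight combination of S₁ and S₂ can dilute a strong single-part
  signal across 5 df, and no optimal reweighting of the two parts is
  provided.
* No parameter estimation: the package tests H₀ only; ω̂ is the only
  model quantity it estimates, and only as a plug-in.
* No stratification or adjustment covariates.
* Missing genotypes or pre-immune status drop the subject (with a logged
  count) rather than being imputed.
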