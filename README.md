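# twistest

A two-part score test (**TWIST** — TWo-part Improper Survival Test) for
assessing the effect of a bi-allelic genetic marker on a semi-continuous
time-to-event outcome that mixes three kinds of subjects:

* **pre-immune** subjects, who already carry the outcome at baseline and
  contribute a point mass at time zero;
* **immune-reactive** subjects, who experience the event at a finite time;
* **immune-tolerant** subjects, who never experience it and contribute a
  point mass at infinity (a *defective*, or improper, survival
  distribution).

The motivating application is drug immunogenicity: the time to first
detection of anti-drug antibodies (ADA) after the first administration of a
biotherapeutic, screened against candidate genetic variants. The package
also ships the mechanistic data-generating model, a two-part logrank
comparator (TLRT), a Monte-Carlo power-study engine, and a multi-variant
screening mode with Benjamini–Hochberg FDR control.

## The model and the statistic

For genotype dummies (G₁, G₂) — G₁ = 0, 1, 2 for [AA], [Aa], [aa] and
G₂ = 1 for the heterozygote — the two-part model is

* a logistic pre-immune part, π(G₁) = expit(θ + βG₁);
* for non-pre-immune subjects, an improper survival function obtained by
  marginalising a latent B-cell-clone mechanism: the clone count K follows
  a Katz-family distribution (mean parameter ω, dispersion γ = γ₁G₁ + γ₂G₂)
  and each clone's detection hazard is scaled by a Gamma(1, τ·e^{α₁G₁+α₂G₂})
  affinity. The reference group has

  S(t) = exp{−ω[1 − (1 + H₀(t)τ)⁻¹]},

  with tail defect S(∞) = e^{−ω}; carriers have the Katz-exponent form with
  tail defect (1 − γG)^{ω/γG}.

The null hypothesis H₀: β = α₁ = α₂ = γ₁ = γ₂ = 0 (no genotype effect on
either part) is tested by S = S₁ + S₂ ~ χ²₅, where

* S₁ is the score chi-square of β in the logistic part,
* S₂ = Û′Î⁻¹Û is a weighted-logrank-type score on the non-pre-immune
  subjects with components Û_a = Σᵢ δᵢ W_a(tᵢ){gₐᵢ − ḡₐ(tᵢ)}; the affinity
  components (α₁, α₂) use the weight W₁(t) = 1 − 2Λ̂(t⁻)/ω̂ and the
  dispersion components (γ₁, γ₂) use W₂(t) = 1 − Λ̂(t⁻)/ω̂, with Λ̂ the
  left-continuous Nelson–Aalen estimator on the pooled non-pre-immune
  sample and ω̂ = Λ̂(t_max) its terminal value.

Degenerate configurations (no pre-immune subjects, monomorphic variant,
absent heterozygotes) reduce the degrees of freedom and are flagged rather
than erroring.

## Worked example

Simulate a null cohort of 400 subjects and test it:

```
$ twistest simulate --seed 42 --n 400 --out ada.csv
$ twistest test ada.csv
variant_id   n  n_preimmune  n_events       S1       S2  statistic  df  p_value flags
     TWIST 400           46       172 1.178977 2.345164   3.524141   5 0.619738
      TLRT 400           46       172 3.654077 1.147142   4.801218   4 0.308308
```

46 subjects are pre-immune (point mass at zero), 172 experience the event,
and 182 are censored — the censored group contains the immune-tolerant
fraction (tail defect 0.5 by default). Under this null draw the TWIST
statistic 3.52 on 5 df (p = 0.62) and the TLRT 4.80 on 4 df (p = 0.31)
correctly find nothing: S₁ is the pre-immune part, S₂ the survival part.

Other entry points:

```
twistest fixtures --outdir fixtures          # deterministic synthetic inputs
twistest screen genotypes.csv subjects.csv --out screen.csv   # BH FDR at 10%
twistest power-study fixtures/power_grid.yaml --out power.csv # scenario grid
```

or from Python:

```python
import twistest as tw
data = tw.generate_dataset(tw.Scenario(n=1000, seed=1))
result = tw.twist_test(data)       # TestResult(statistic, df, p_value, ...)
```

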