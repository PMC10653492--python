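# ggfrailty

Detecting **mortality deceleration** — the slowing of the death-rate
increase at the oldest ages — from life-table data, without a p-value.

`ggfrailty` fits the gamma-Gompertz frailty model to death counts D_x and
person-years exposures E_x over one-year age intervals. Individual hazards
follow the Gompertz law μ(x) = a·e^{bx}; multiplying by a gamma frailty
with mean 1 and variance σ² gives the population hazard

    μ̄(x) = a e^{bx} / (1 + σ² (a/b)(e^{bx} − 1)),

which plateaus at b/σ². Deceleration is present exactly when σ² > 0, a
parameter on the boundary of its space where standard tests misbehave.
With D_x Poisson(E_x μ̄(x; θ)), the package maximises either

* the log-likelihood ℓ(θ) = Σ [D_x ln μ̄(x;θ) − E_x μ̄(x;θ)]  (**ML**), or
* the penalized ℓ_p(θ) = ℓ(θ) − λ(σ² + ln σ²), λ = ½ by default (**MAP**):
  a shrinkage estimator equivalent to a gamma(1−λ, λ) prior on σ², which
  returns σ̂² **exactly 0** when the data show no deceleration and nearly
  the ML estimate when they do.

The package is aimed at demographers and biostatisticians studying
old-age mortality plateaus: it ships the closed-form model functions, the
two estimators with observed-information standard errors and Wald
intervals, a cohort simulator, a Monte Carlo harness for estimator
bias/SD and detection error rates, readers for CSV and HMD-style 1x1
Deaths/Exposures text tables, and a CLI.

## Worked example

Simulate a 10,000-person cohort with real heterogeneity (σ² = 0.2) and one
without, then fit both ways:

```python
from ggfrailty import (ThetaGG, sample_lifespans, build_life_table,
                       fit, detect_deceleration)

for s2 in (0.2, 0.0):
    truth = ThetaGG(a=0.0001, b=0.1, sigma2=s2)
    lt = build_life_table(sample_lifespans(10_000, truth, rng_seed=7))
    for method in ("ML", "MAP"):
        fr = fit(lt, method, seed=1)
        e = fr.theta_hat
        print(f"truth sigma2={s2}: {method:4s} a={e.a:.6f} b={e.b:.6f} "
              f"sigma2={e.sigma2:.6f} decision={detect_deceleration(fr)}")
```

prints (fitted level a, rate of aging b, frailty variance σ²):

```
truth sigma2=0.2: ML   a=0.000113 b=0.098314 sigma2=0.169900 decision=deceleration
truth sigma2=0.2: MAP  a=0.000114 b=0.098239 sigma2=0.168510 decision=deceleration
truth sigma2=0.0: ML   a=0.000104 b=0.100096 sigma2=0.000000 decision=no_deceleration
truth sigma2=0.0: MAP  a=0.000104 b=0.100096 sigma2=0.000000 decision=no_deceleration
```

Under heterogeneity both estimators agree closely (MAP's 95% Wald interval
for σ² is (0.129, 0.208)); on the Gompertz cohort MAP reports σ̂² = 0 —
the decision *is* the estimate, no significance level needed — while ML
lands at a raw ~10⁻¹³ with no usable standard error in the flat region.

The same analysis from the shell:

```sh
ggfrailty --seed 1 simulate --a 0.0001 --b 0.1 --sigma2 0 --n 10000 --out cohort
ggfrailty --seed 1 fit cohort.csv --method map        # prints sigma2 = 0.0
ggfrailty --seed 1 compare cohort.csv                 # ML vs MAP by MSE
ggfrailty --seed 1 mc-study --reps 200 --out-dir study/
```

`fit` also reads HMD-dialect files directly:
`ggfrailty fit --deaths Deaths_1x1.txt --exposures Exposures_1x1.txt
--year 2009 --sex Female --min-age 70 --method map`.

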