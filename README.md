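# medsurv

Nonparametric comparison of **median survival times** across K groups of
right-censored data, for biostatisticians and epidemiologists who need to ask
"do these arms have the same median survival?" rather than "are the whole
survival curves equal?" — the question the log-rank test answers. When curves
cross, or differ only in shape, the medians can agree while the curves do
not, and a median-directed test is the appropriate instrument.

## The statistic

For group *i* with right-censored observations (Z_ij, δ_ij), let F̂_i be the
Kaplan–Meier survival estimate and θ̂₀ the Kaplan–Meier median of the pooled
sample. With η_i = F̂_i(θ̂₀), the test statistic is the Cochran-type
inverse-variance-weighted heterogeneity measure

    C = Σᵢ wᵢ (ηᵢ − Σⱼ hⱼ ηⱼ)²,   wᵢ = 1/σ̂ᵢ²,   hᵢ = wᵢ / Σⱼ wⱼ,

which is asymptotically χ² with K − 1 degrees of freedom when all groups
share a common median (each ηᵢ is then asymptotically normal around 0.5).

The variance estimate σ̂ᵢ² is what makes the test honest in small samples.
The Greenwood formula captures only the expected conditional variance of the
survival estimate and underestimates the total variance, inflating the
weights and hence the type I error rate of any Cochran-type statistic. The
**composite** estimate adds a closed-form proxy for the missing component:
with θ̂ᵢ the group median and θ̂ᵢ₁ the uncensored time closest to it,

    σ̂ᵢ² = Greenwood(F̂ᵢ at θ̂₀) + [F̂ᵢ(θ̂ᵢ) − F̂ᵢ(θ̂ᵢ₁)]² / 2.

The correction is of order nᵢ⁻², so the `greenwood_only` variant (correction
dropped) converges to the same statistic for large groups while exposing the
small-sample inflation.

## Worked example

```python
import numpy as np
from medsurv import GroupedSurvivalData, SurvivalSample, median_survival_test

rng = np.random.default_rng(7)
control = SurvivalSample(rng.exponential(10.0, 40), np.ones(40, int), "control")
treated = SurvivalSample(rng.exponential(17.0, 40), np.ones(40, int), "treated")
res = median_survival_test(GroupedSurvivalData([control, treated]))
print(res.summary())
```

prints

```
K-sample median survival test (composite variance)
  statistic C = 10.5660   df = 1   p-value = 0.0012
  pooled median = 9.67
         group   n/a-median      eta   variance
       control        6.347   0.3250   0.005797
       treated        14.81   0.6750   0.005797
```

Reading it: the pooled-sample median survival is 9.67 time units; only 32.5 %
of the control group but 67.5 % of the treated group survive past that point,
and weighting those deviations by their inverse variances gives C = 10.57 on
1 degree of freedom — p ≈ 0.001, so the medians differ.

The same analysis from a CSV file with `time,event,group` columns
(`event` = 1 for an observed event, 0 for censored):

```
medsurv test mystudy.csv                 # composite variance (default)
medsurv test mystudy.csv --variant greenwood_only
```

Monte-Carlo size/power for any catalog scenario, e.g. the four-group
small-sample exponential null at 20 % censoring:

```
medsurv simulate --table 4 --row exponential --rate 0.2 \
    --reps 10000 --seed 1 --out summary.csv
```

`medsurv fixture toy_uncensored --path toy.csv` writes a hand-checkable
demo table.

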