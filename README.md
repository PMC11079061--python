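# dielniche

Temporal-niche analysis for camera-trap surveys: when are sympatric species
active over the 24-h cycle, and how much do their activity rhythms overlap?

Camera traps record a time-stamped photo stream per site.  `dielniche` turns
such streams into diel activity densities and pairwise overlap statistics,
the standard currency of temporal-niche partitioning studies in community
ecology — e.g. asking whether wild ungulates shift their activity away from
domestic livestock, or whether two competing deer species divide the day
between them.

## The method

1. **Independent events.** Consecutive photographs of a species at one
   camera are collapsed into a single event unless separated by more than
   30 min (configurable); the event keeps its first photo's time.
2. **Solar time.** Clock time is biologically arbitrary (dawn drifts by
   hours over a year), so event times are mapped onto a sun-anchored circle:
   sunrise ↦ π/2, sunset ↦ 3π/2 each day, with linear interpolation inside
   day and night.  Sunrise/sunset come from the NOAA solar equations at the
   reserve-center coordinates.
3. **Circular KDE.** Each species–season sample of solar times gets a von
   Mises kernel density `f̂(t) = (1/n) Σᵢ exp(c·cos(t−xᵢ)) / (2π I₀(c))`,
   with the kernel concentration `c` (an inverse bandwidth) set by a plug-in
   rule from the sample's von Mises concentration κ̂.
4. **Overlap coefficient Δ.** The area under the pointwise minimum of two
   activity densities: Δ = 0 disjoint niches, Δ = 1 identical.  `Δ̂1`
   integrates the fitted densities on a grid (used when either sample has
   ≤ 50 events); `Δ̂4` averages density ratios at the observed points (used
   when both exceed 50).  Δ < 0.50 is reported as low overlap, 0.50–0.80
   medium, > 0.80 high.
5. **Inference.** 95 % CIs from 1,000 smoothed bootstraps (resampling the
   fitted kernel density); equality of two diel distributions is tested by a
   randomization test that resamples pseudo-pairs from the pooled events and
   locates the observed Δ in the null's lower tail.

Because raw survey data from protected areas are typically access-restricted,
the package ships a synthetic scene generator whose ground truth is known von
Mises mixtures (nocturnal, crepuscular, cathemeral and diurnal archetypes),
plus an analytic quadrature oracle for the true overlap of any two mixtures —
so the whole pipeline is testable end to end.

## A worked example

```python
import numpy as np
from dielniche import (ARCHETYPES, analytic_overlap, bootstrap_ci,
                       estimate_overlap, randomization_test,
                       sample_mixture, substream)

rng = np.random.default_rng(2)
nocturnal   = sample_mixture(400, ARCHETYPES["nocturnal"], rng)
crepuscular = sample_mixture(400, ARCHETYPES["crepuscular"], rng)

est  = estimate_overlap(nocturnal, crepuscular)
ci   = bootstrap_ci(nocturnal, crepuscular, reps=1000, rng=substream(2, "ci"))
test = randomization_test(nocturnal, crepuscular, reps=1000,
                          rng=substream(2, "test"))
print(est.estimator.value, f"{est.delta:.3f}", f"[{ci.low:.3f}, {ci.high:.3f}]",
      f"p={test.p_value:.4f}", est.category.value)
```

prints

```
Dhat4 0.430 [0.398, 0.500] p=0.0010 low
```

i.e. a nocturnal and a crepuscular species share 43 % of their activity
density (the generating mixtures' true overlap is 0.427), the 95 % CI spans
0.40–0.50, and the randomization test rejects identical diel patterns —
a low-overlap pair, consistent with temporal niche separation.

The full pipeline is one call (or `dielniche run` from a shell):

```python
from dielniche import AnalysisConfig, run_analysis, write_report
result = run_analysis("detections.csv", AnalysisConfig(seed=42))
write_report(result, "report/")
```

producing `table1_seasonal.csv` (each species' cold-vs-warm overlap),
`table2_pairwise_cold.csv` / `_warm.csv` (all species pairs with estimator,
Δ, CI, p and category), per-sample density curves and a JSON manifest
recording every analysis decision in force.  See `examples/` for narrative
scripts covering each capability.

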