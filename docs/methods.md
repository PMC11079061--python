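# Methods

This note documents the statistical model, the defaults and the design
choices behind `dielniche`, in the spirit of a package vignette.  Nothing
here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Independent events

The unit of analysis is the independent detection event.  Within each
(site, species) stream sorted by time, a photograph opens a new event iff it
is the first of the stream or its gap to the **immediately preceding**
photograph exceeds the independence interval (default 30 min).  This is the
chain rule: a burst of photographs 20 min apart can extend an event
indefinitely, because "consecutive … more than 30 min apart" refers to
adjacent records, not to the event's first photo.  A gap of exactly 30 min
does **not** break an event (strict "more than").  Grouping is per camera
site and species — the field convention, matching per-camera deployment;
pooling sites before filtering would merge simultaneous detections at
distant cameras.  Multi-animal triggers count once: events, not individuals,
are the currency.

Season labels use the calendar month of the event's local civil date.
Default: warm = April–September, cold = October–March, the climatic split of
the temperate-monsoon demo system.  The two month sets must partition the
year, so assignment is total.

## Solar time

Let `rise(d)` and `set(d)` be local sunrise/sunset on date `d` at the
reserve-center coordinates (default 33.48° N, 111.95° E, UTC+8 — the demo
reserve's bounding-box midpoint; all three are configurable).  The
double-anchored map sends

- `rise(d) ↦ π/2` and `set(d) ↦ 3π/2` exactly,
- daytime clock times linearly onto (π/2, 3π/2),
- night times linearly onto (3π/2, 2π) ∪ [0, π/2), across the night interval
  that actually spans the moment (previous sunset → next sunrise, computed
  from both days' sun times so there is no discontinuity at midnight).

This makes dawn/dusk activity comparable across dates and seasons; solar
noon is always π and solar midnight 0.  The map is strictly increasing and
invertible within a day; the inverse is what the scene generator uses, and
round-trips are exact to < 1e-9 rad.

Sunrise/sunset use the NOAA solar-position equations (fractional year,
equation of time, declination, hour angle at zenith 90.833°), accurate to a
minute or two at mid-latitudes — well inside the minute-level resolution of
camera timestamps.  Polar latitudes (|φ| ≥ 66.5°) are rejected explicitly.
A fixed UTC offset is required; no daylight-saving logic is attempted.

## Circular kernel density estimation

A species–season sample x₁…xₙ of solar radians gets the von Mises KDE

    f̂(t) = (1/n) Σᵢ exp(c·cos(t − xᵢ)) / (2π I₀(c)),

evaluated with exponentially scaled Bessel functions so any concentration is
overflow-safe.  The kernel concentration `c` (inverse-bandwidth analogue)
follows the Taylor-type plug-in rule

    c = [ 3 n κ² I₂(2κ) / (4 √π I₁(κ)²) ]^{2/5} × adjust .

**Estimating κ for the bandwidth.**  The plain ML estimate (solving
A(κ) = I₁(κ)/I₀(κ) = R̄ on the first trigonometric moment) is exposed as
`fit_kappa_ml` and stored on the fitted object, but it is the wrong input to
the plug-in rule for multimodal activity: a crepuscular species with
near-antipodal dawn/dusk peaks has R̄ ≈ 0, κ̂ ≈ 0, and the rule would
collapse `c` and smooth the two peaks into a near-uniform density.  The
bandwidth therefore uses `fit_kappa_moments`: solve A_p(κ) = R̄_p for each
trigonometric-moment order p = 1..3 and take the largest κ.  For unimodal
von Mises data all orders agree; for bimodal data the second moment still
sees the peaks' concentration.  This mirrors the reference ecosystem's
bandwidth helper, which exposes the moment order for exactly this reason.
If every moment cancels (exactly symmetric data), `c` falls back to
1.0 × adjust with a warning.

`adjust` defaults to 0.8 when the density feeds Δ̂1 and 1.0 when it feeds
Δ̂4 — the published recommendation accompanying the two estimators.  No
bandwidth cross-validation is attempted (out of scope by design).

Fitting requires n ≥ 10 (hard error naming the species/season) and warns
below 25, where overlap estimates are known to be unstable.  Densities are
checked to integrate to 1 within 1e-4 on a 512-point trapezoid grid.

## Overlap coefficients

Δ = ∫ min(f₁, f₂) over the circle.  Two estimators:

- **Δ̂1**: trapezoid integral of min(f̂₁, f̂₂) on a 128-point grid (the
  ecosystem default; configurable).  For smooth von Mises mixtures the
  128-point grid agrees with an 8192-point quadrature to < 1e-3.
- **Δ̂4**: ½[ mean_i min(f̂₂(x₁ᵢ)/f̂₁(x₁ᵢ), 1) + mean_j min(f̂₁(x₂ⱼ)/f̂₂(x₂ⱼ), 1) ],
  clamped to [0, 1].  von Mises kernels are strictly positive, so the ratios
  are always defined.

**Selection rule**: Δ̂4 iff *both* samples exceed 50 events, else Δ̂1.  The
smaller sample governs because its finite-sample bias dominates; exactly 50
is not "> 50" and selects Δ̂1 (deterministic, conservative).  Which
estimator was used is printed for every pair in the reports.

Categories: Δ < 0.50 low, 0.50–0.80 medium (both boundaries inclusive,
reading the conventional "0.50–0.80" band as a closed interval), > 0.80 high.

Both estimators are exactly symmetric in their arguments, and identical
samples give Δ = 1 (Δ̂4 exactly; Δ̂1 to quadrature precision).

## Resampling inference

- **CI**: 1,000 smoothed bootstraps by default — each replicate draws both
  samples from their own fitted KDEs (observed point + von Mises(0, c)
  noise) at the original sizes, refits, and recomputes Δ with the *same*
  estimator as the point estimate.  The percentile interval is reported;
  the bias-corrected variant is left as future work.  Bootstrap CIs need
  not contain the point estimate.
- **Test**: the null distribution of Δ is built by drawing pseudo-samples of
  the original sizes with replacement from the pooled **raw** events (not
  from a smoothed pooled density — the null is about the empirical data).
  One-tailed: equality is rejected for unusually *low* overlap, with
  p = (1 + #{Δ_null ≤ Δ_obs}) / (reps + 1), never zero.  The suite
  calibrates this test by simulation: same-distribution pairs at n = 100
  reject at α = 0.05 at a rate inside [0.02, 0.08].
- **No multiplicity correction** is applied across the pairwise tests;
  reported p-values are raw, as is common in this literature.  This is
  stated in the run manifest.

**Determinism.**  One run-level seed; every (task, species pair, season)
gets its own substream via a hash of the tokens, so adding a species does
not shift any other pair's stream, and reruns are byte-identical.

## Synthetic scenes

The generator emulates a two-year, 62-camera survey of a six-species
ungulate community.  Ground-truth diel densities are von Mises mixtures on
the solar circle:

- nocturnal: 0.7·vM(7π/4, 3) + 0.3·vM(π/4, 3) (two night lobes),
- crepuscular: 0.5·vM(π/2, 6) + 0.5·vM(3π/2, 6) (dawn + dusk),
- diurnal: vM(π, 3),
- cathemeral: 0.8·uniform + 0.2·vM(π, 1),

chosen once to mimic the community's qualitative activity shapes — they are
generator defaults, not estimates of any real density.  Expected event
counts per species default to the community's published scale (87, 162,
794, 106, 2588, 123 events, split evenly between seasons), so small-sample
species genuinely exercise the Δ̂1 path.  Each species' cold mixture is a
phase-shifted copy of its warm one (a tunable season-shift knob; the roe
deer, boar and sheep shift noticeably, the others barely).

Event counts are Poisson; each event's solar radian is drawn from the true
mixture and inverted through the solar map on a random in-season date at a
random site, then expanded into a 3-photo burst 10 s apart.  Events of one
species at one site are kept strictly further apart than the independence
interval (collisions are re-sited or re-dated), so the filter recovers the
generated event count exactly; an optional clutter fraction adds straggler
photos *within* 30 min of an event, which must not change the event count.
What the generator does **not** emulate: detection probability varying with
distance or habitat, weather covariates, camera failures, or spatial
autocorrelation of animal movement.  Passing tests therefore demonstrate
correctness of the estimators on known ground truth, not robustness to
field-data pathologies.

`analytic_overlap` — high-resolution (8192-point, convergence-checked)
trapezoid quadrature of min of two true mixture densities — is the
independent oracle for every recovery test, kept deliberately separate from
the estimator code paths.

## Problem sizes and tolerances

Oracle-equivalence checks use ten fixed mixture pairs: Δ̂1 on analytic
densities to 1e-3, Δ̂4 at n = 10,000 to 0.03.  Type-I calibration uses 500
simulated same-distribution pairs (n = 100) at 200 randomization reps;
power uses five anti-phase pairs (κ = 4, n = 200) at 500 reps.  Pipeline
ground-truth recovery runs a four-archetype scene at 600 events per
species-season and requires every pair's Δ within 0.05 of the analytic
truth.  Report-generating tests and the acceptance script use 100
resampling reps — the minimum the API accepts — because point estimates do
not depend on rep count; production defaults are 1,000.

## Known limitations

- The plug-in bandwidth assumes a von Mises-like reference; heavily
  multi-peaked densities beyond bimodal may still be over-smoothed.
- Δ̂ estimates below ~25 events per sample are unstable (the package warns);
  below 10 it refuses.
- The percentile bootstrap can undercover for Δ near 1, where the statistic
  is boundary-limited.
- Sunrise/sunset are computed at a single reference point; surveys spanning
  several degrees of longitude should segment sites into zones.
- The randomization test conditions on pooled event times and tests
  distributional equality, not independence of the two streams.
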