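"""Estimate the temporal overlap of two species and test for a difference.

Delta is the shared area under two activity densities (0 = disjoint diel
niches, 1 = identical).  Because the true mixtures are known here, the
estimate can be compared with the analytic overlap computed by quadrature.
"""

import numpy as np

from dielniche import (
    ARCHETYPES, analytic_overlap, bootstrap_ci, estimate_overlap,
    randomization_test, sample_mixture, substream,
)

rng = np.random.default_rng(2)
nocturnal = sample_mixture(400, ARCHETYPES["nocturnal"], rng)
crepuscular = sample_mixture(400, ARCHETYPES["crepuscular"], rng)

est = estimate_overlap(nocturnal, crepuscular)
ci = bootstrap_ci(nocturnal, crepuscular, reps=1000, rng=substream(2, "ci"))
test = randomization_test(nocturnal, crepuscular, reps=1000,
                          rng=substream(2, "test"))
truth = analytic_overlap(ARCHETYPES["nocturnal"], ARCHETYPES["crepuscular"])

print(f"estimator: {est.estimator.value} (both n > 50)")
print(f"Delta = {est.delta:.3f}  [{ci.low:.3f}, {ci.high:.3f}] 95% CI")
print(f"true overlap of the generating mixtures: {truth:.3f}")
print(f"randomization p = {test.p_value:.4f} -> "
      f"{'different' if test.significant else 'indistinguishable'} diel patterns")
print(f"overlap category: {est.category.value}")
# The CI comes from 1000 smoothed bootstraps (resampling the fitted kernel
# density); the p-value locates the observed Delta in the null distribution
# built by resampling pseudo-pairs from the pooled sample.
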