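"""Run the whole analysis on a simulated survey and print the report tables.

Stages: photo table -> independent events -> season labels -> solar times ->
per-season densities -> seasonal comparison (one row per species) and
pairwise overlap matrices per season, each with bootstrap CI and
randomization p.
"""

import numpy as np

from dielniche import (
    AnalysisConfig, default_scene_spec, generate_scene, run_analysis,
    write_report, write_scene,
)

spec = default_scene_spec()
frame, truth = generate_scene(spec, np.random.default_rng(3))
write_scene(frame, truth, "demo_detections.csv")

# 200 resampling reps keep this demo tractable (a few minutes; the wild-boar
# pairs dominate at n ~ 1300); production runs use the 1000-rep defaults of
# AnalysisConfig.
config = AnalysisConfig(bootstrap_reps=200, randomization_reps=200, seed=42)
result = run_analysis("demo_detections.csv", config)

print("— seasonal comparison (cold vs warm activity of each species) —")
print(result.seasonal.to_string(index=False))
print("\n— cold-season pairwise overlap (first rows) —")
print(result.pairwise_cold.head(6).to_string(index=False))

files = write_report(result, "demo_report")
print(f"\nwrote {len(files)} report files to demo_report/ "
      "(tables, manifest, density curves)")
# Species whose seasonal delta is low with p < 0.05 (here the sheep, whose
# peak shifts between morning and afternoon) genuinely shift their diel
# rhythm between seasons; high-delta species keep the same rhythm year-round.
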