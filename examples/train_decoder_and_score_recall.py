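"""Train the multi-region decoder on a synthetic viewing epoch and score
concept reinstatement during recall with the Memory Confidence Score.

A small study is generated: 2 bundles of 8 microwires, a 168-s viewing
epoch in which 4 concepts appear on schedule (their assigned channels
fire at 3x the background rate while on screen, i.e. gamma = 2), and a
recall epoch in which 3 concepts are each vocalized 5 times with the
concept pattern injected during the 4 s before each vocalization.
"""

import numpy as np

from memdecode.model.network import ModelConfig, TrainingConfig
from memdecode.pipeline import SyntheticStudy, fit_decoder, score_study
from memdecode.synthetic import SimulationSpec, random_schedule

schedule = random_schedule(4, 168.0, seed=7)

spec = SimulationSpec(n_regions=2, n_concepts=4, episode_duration_s=168.0,
                      effect_size=2.0, concept_schedule=schedule, seed=7)
study = SyntheticStudy(spec, vocab=[f"word{i}" for i in range(20)],
                       n_concept_vocalizations={0: 5, 1: 5, 2: 5})

model_cfg = ModelConfig(hidden_size=48, intermediate_size=96, depth=2,
                        heads=4, n_concepts=4, seed=7)
train_cfg = TrainingConfig(lr=2e-3, epochs=8, batch_size=64,
                           min_combination_screentime_s=2.0, seed=7)
model, history = fit_decoder(study.viewing_regions, study.labels,
                             model_cfg, train_cfg)
print("training loss per epoch:", [round(l, 3) for l in history["loss"]])

res = score_study(model, study, n_surrogates=500, seed=7)
for concept, r in sorted(res["mcs"].items()):
    print(f"concept {concept}: MCS = {r.mcs:.1f} "
          f"(A_real = {r.a_real:.4f}, n = {r.n_vocalizations} vocalizations)")
pooled = res["pooled"]
print(f"pooled vs chance 50: Z = {pooled['z']:.2f}, p = {pooled['p']:.3f}, "
      f"D = {pooled['d']:.2f}")
print("MCS near 100 means pre-vocalization activation exceeded nearly every "
      "surrogate draw; 50 is chance.")
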