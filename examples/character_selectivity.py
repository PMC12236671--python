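"""Character-selectivity analysis on simulated sorted units.

40 Poisson units are simulated over a 600-s viewing period; 3 of them
triple their firing rate whenever their character is on screen. The
sign-flip permutation t-test should flag (only) those units.
"""

import numpy as np

from memdecode.selectivity import (CharacterAppearance, SortedUnit,
                                   classify_units, filter_units,
                                   score_unit_character)
from memdecode.synthetic import simulate_units

rng = np.random.default_rng(5)
schedule = {
    "A.Fayed": [(t, t + 2.0) for t in np.arange(10.0, 590.0, 12.0)],
    "J.Bauer": [(t, t + 2.0) for t in np.arange(16.0, 590.0, 12.0)],
}
spikes, _ = simulate_units(40, 600.0, base_rate_hz=2.0,
                           character_schedule=schedule, rate_gain=3.0, seed=5,
                           unit_character={0: "A.Fayed", 1: "A.Fayed",
                                           2: "J.Bauer"})
units = filter_units([SortedUnit(i, s) for i, s in enumerate(spikes)], 600.0)
apps = {c: [CharacterAppearance(c, a, b) for a, b in iv]
        for c, iv in schedule.items()}
verdicts = []
for u in units:
    for c, a in apps.items():
        verdicts.append(score_unit_character(u, a, seed=100 + u.unit_id))
classes = classify_units(verdicts)
sel = [uid for uid, c in classes.items() if c == "selective"]
print(f"{len(units)} units pass the 0.5 spk/s rate filter")
print(f"selective units (p<0.01, coverage>30%, single character): {sorted(sel)}")
print("ground truth: units 0, 1 respond to A.Fayed; unit 2 to J.Bauer. "
      "The remaining units are homogeneous Poisson, so at p<0.01 over "
      f"{2 * (len(units) - 3)} null tests roughly one false flag is expected.")
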