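"""Channel-subset (ablation) selection on the shipped microwire
localization table.

Builds a per-participant channel map from the bundled region counts and
shows which ablation models each participant can run: a model is only
defined when the mode leaves at least one intact 8-wire bundle.
"""

from importlib import resources

import pandas as pd

from memdecode.controls import ABLATION_MODES, ChannelMap, select_channels

table = pd.read_csv(resources.files("memdecode.data")
                    .joinpath("microwire_regions.csv"))

for _, row in table.iterrows():
    bundle_map, region_map, ch = {}, {}, 0
    bundle = 0
    for region in ("hpc", "amy", "phc", "ent", "pfc", "acc"):
        for _ in range(int(row[region]) // 8):
            for _ in range(8):
                bundle_map[ch] = bundle
                region_map[ch] = region.upper()
                ch += 1
            bundle += 1
    cmap = ChannelMap(bundle_map, region_map)
    available = []
    for mode in ABLATION_MODES:
        try:
            n = len(select_channels(cmap, mode))
            available.append(f"{mode}({n})")
        except ValueError:
            available.append(f"{mode}(--)")
    print(f"{row['participant']:>4}: {' '.join(available)}")
print("\n'--' marks modes that would leave no channels; such a "
      "participant is excluded from that ablation model.")
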