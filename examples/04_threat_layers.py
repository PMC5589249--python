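"""Build the six per-threat layers from raw synthetic inputs.

Chains each threat's documented transform (resample, square root, min-max
normalization, seasonal fire weighting, province production splitting,
point-to-pixel mining, scenario-based climate rules) and prints the class
tallies that result from classifying each at full sensitivity.
"""

import numpy as np

from threatscape.grid import CLASS_NAMES, GridSpec
from threatscape import combine, sdm, synthetic, threats

spec = GridSpec(n_rows=60, n_cols=80, origin_lon=-6.0, origin_lat=15.5)
inputs = synthetic.gen_threat_inputs(spec, seed=1)
climate = synthetic.gen_climate(spec, seed=1)


def tally(classes):
    counts = np.bincount(classes.ravel(), minlength=5)
    return ", ".join(f"{name}:{c}" for name, c in zip(CLASS_NAMES, counts) if c)


over = threats.overexploitation_intensity(inputs["footprint"], spec)
print("overexploitation:", tally(combine.classify_magnitude(over.layer.values)))

tlu_layer = threats.tlu(inputs["cattle"], inputs["goats"], inputs["sheep"])
print(f"TLU per cell: 0-{tlu_layer.values.max():.0f} "
      "(0.7 per head of cattle, 0.1 per goat or sheep)")
graze = threats.overgrazing_intensity(tlu_layer)
print("overgrazing:", tally(combine.classify_magnitude(graze.layer.values)))

freq = threats.fire_frequency(inputs["fire_events"], spec, (2007, 2012))
fire = threats.fire_intensity(freq)
print("fire:", tally(combine.classify_magnitude(fire.layer.values)))

cotton = threats.cotton_intensity(
    inputs["cotton_stats"], inputs["cotton_mask"], inputs["province_map"]
)
print("cotton (capped at High):",
      tally(combine.classify_magnitude(cotton.layer.values, capped=True)))

mining = threats.mining_class(inputs["mining_points"], spec)
print("mining:", tally(mining.classes))

# Climate threat needs a species model: fit one quickly and apply the rules.
niche = next(iter(synthetic.default_niches(climate["current"]).values()))
occ = synthetic.gen_occurrences(niche, climate["current"], 200, seed=2)
model = sdm.calibrate_ensemble(occ, climate["current"], n_repeats=1, seed=3)
p45 = sdm.predict_presence(model, climate["rcp45"], "tpr90")
p85 = sdm.predict_presence(model, climate["rcp85"], "tpr90")
n45 = sdm.detect_novel(climate["current"], climate["rcp45"], model.retained_variables)
n85 = sdm.detect_novel(climate["current"], climate["rcp85"], model.retained_variables)
clim = threats.climate_class(p45, p85, n45, n85)
print("climate change:", tally(clim.classes))
# Each line counts grid cells per magnitude class; sqrt+min-max transforms
# tame the skew of the grazing and fire intensity distributions, and the
# climate layer reflects habitat loss and novel-climate exposure by 2055.
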