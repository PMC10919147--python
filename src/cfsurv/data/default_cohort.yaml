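# Default synthetic-cohort configuration, version 1.
# Covariate marginals follow the published registry cohort's baseline table
# (counts pooled over both treatment arms); survival scale targets a median
# near 12 months with ~90/10 chemoradiotherapy/radiotherapy selection that
# depends on age, and a treatment effect that attenuates with age and male
# sex and reverses for ventricular-system extension.
version: 1
n: 5000
seed: 0
horizon: 120.0
continuous:
  age: {mean: 62.0, sd: 11.9, low: 18.0, high: 95.0}
  tumor_size: {mean: 45.0, sd: 17.8, low: 5.0, high: 150.0}
categorical:
  sex: {female: 0.4062, male: 0.5938}
  race: {white: 0.8957, other: 0.1043}
  married: {"no": 0.3198, "yes": 0.6802}
  urban: {"no": 0.1156, "yes": 0.8844}
  region: {midwest: 0.6426, east: 0.1756, south: 0.1734, oversea: 0.0084}
  income: {low: 0.2657, high: 0.7343}
  location:
    frontal: 0.3103
    temporal: 0.3005
    parietal: 0.1744
    occipital: 0.0483
    cerebellum: 0.0071
    cerebrum: 0.0189
    brainstem: 0.0017
    ventricle: 0.0023
    overlapping: 0.1365
  laterality: {left: 0.4328, mid: 0.0835, right: 0.4837}
  extension: {confined: 0.8567, ventricular_system: 0.0266, midline: 0.1167}
  metastasis: {"no": 0.6736, "yes": 0.3264}
  eor: {biopsy: 0.1949, STR: 0.2379, GTR: 0.2871, SpTR: 0.2801}
propensity:
  target_mean: 0.898
  coefficients:
    age: -0.8
    "married=yes": 0.25
    "eor=biopsy": -0.3
weibull:
  shape: [1.1, 1.1]
  scale: [10.5, 10.5]
hazard:
  base:
    age: 0.35
    "sex=male": 0.05
    "eor=biopsy": 0.30
    "eor=GTR": -0.20
    "eor=SpTR": -0.30
    "metastasis=yes": 0.15
    "extension=midline": 0.10
    "extension=ventricular_system": 0.20
    tumor_size: 0.10
  treatment_intercept: -0.8
  treatment_modifiers:
    age: 0.35
    "sex=male": 0.25
    "extension=ventricular_system": 1.6
censoring:
  rate: 0.016
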