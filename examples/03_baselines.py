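"""Classical resampling baselines: SMOTE, random over-/under-sampling."""

import numpy as np

from pseudoneg import (
    BaselineConfig,
    LabeledDataset,
    random_oversample,
    random_undersample,
    smote,
)

rng = np.random.default_rng(3)
X = np.vstack([rng.normal(1.0, 1.0, (15, 5)), rng.normal(-0.5, 1.0, (85, 5))])
ds = LabeledDataset(X, np.array([True] * 15 + [False] * 85))
print(f"before: {ds.m} positive / {ds.n} negative")

sm = smote(ds, BaselineConfig(method="smote", amount=30, k_neighbors=5, seed=1))
print(f"SMOTE +30 synthetics:    {sm.m} positive / {sm.n} negative")

ros = random_oversample(ds, BaselineConfig(method="ros", amount=30, seed=1))
print(f"ROS +30 duplicates:      {ros.m} positive / {ros.n} negative")

rus = random_undersample(ds, BaselineConfig(method="rus", amount=70, seed=1))
print(f"RUS -70 majority rows:   {rus.m} positive / {rus.n} negative")
# SMOTE interpolates new minority points along segments to k=5 nearest
# minority neighbors; ROS repeats existing rows; RUS discards majority rows.
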