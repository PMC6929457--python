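"""Turn per-residue PSSM scores into window features for binding prediction.

Each residue of a protein gets 20 conservation scores; a sliding window of
9 residues centered on each position, flattened, gives the standard
9 x 20 = 180-dimensional feature vector (zero-padded at sequence ends).
"""

import numpy as np

from pseudoneg import ResidueProfile, describe, pssm_window_features

rng = np.random.default_rng(7)
n_residues = 60
scores = rng.normal(size=(n_residues, 20))          # stand-in for real PSSM rows
labels = rng.random(n_residues) < 0.12               # sparse binding residues
labels[:2] = True                                    # ensure both classes
profile = ResidueProfile(scores=scores, labels=labels, sequence_id="synthetic")

ds = pssm_window_features(profile, window=9)
print(describe(ds, "synthetic-pssm"))
print(f"feature vector length: {ds.n_features} (= 9 residues x 20 scores)")
print(f"first residue, leading padded block all zero: "
      f"{bool((ds.features[0, :80] == 0).all())}")
# With window 9, the first four residues of a sequence have 1-4 leading
# 20-score blocks zero-padded because those positions fall off the N-terminus.
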