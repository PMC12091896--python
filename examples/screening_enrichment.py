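"""Enrichment-factor sweep over decoy-to-active ratios.

Simulates a screening run where actives tend to score higher than decoys,
then computes mean EF over subsampled libraries at several ratios, the
protocol used to assess screening power under class imbalance.
"""

import numpy as np

from agima import ScreeningConfig, rdta_max, screening_protocol

rng = np.random.default_rng(0)
n_actives, n_decoys = 100, 4000
scores = np.concatenate([rng.normal(1.0, 1.0, n_actives),   # actives: shifted up
                         rng.normal(0.0, 1.0, n_decoys)])
labels = np.array([1] * n_actives + [0] * n_decoys)

cfg = ScreeningConfig(top_percents=(1.0, 2.0, 4.0), ratios=(2, 10, 40),
                      repeats=10, seed=1)
result = screening_protocol(scores, labels, cfg)

print(f"library: {n_actives} actives / {n_decoys} decoys "
      f"(r_DTA_max = {rdta_max(n_actives, n_decoys)})")
print("top X%   r_DTA   mean EF")
for (X, r), ef in sorted(result.mean_ef.items()):
    print(f"{X:5.0f}   {r:5d}   {ef:7.2f}")
# EF > 1 means actives are enriched in the top of the ranking; EF shrinks
# toward the ratio ceiling as X grows and as decoys dilute the library
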