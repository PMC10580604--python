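"""Train a per-tissue deep Cox extractor and build the 128-dim vector.

Patches inherit their patient's overall-survival label; a small conv net
with an FC-32 feature layer and a scalar risk head is trained on the
negative log partial likelihood. Per-tissue vectors are patch means
weighted by the tissue's share of sampled patches, then concatenated in
the fixed order TUM, LYM, STR, MUC.
"""

import numpy as np
import pandas as pd

from histoarea import (
    DeepConvSurvConfig,
    TissueClass,
    aggregate_tissue,
    concat_histo,
    generate_patch_images,
    train_tissue_extractor,
)

rng = np.random.default_rng(0)
n_patients, patches_each = 15, 6
surv = pd.DataFrame(
    {
        "patient_id": [f"P{i}" for i in range(n_patients)],
        "time": rng.exponential(1.0, n_patients) + 0.01,
        "event": 1,
    }
)
patches = np.concatenate(
    [
        generate_patch_images(TissueClass.TUM, patches_each, 32, seed=i)
        for i in range(n_patients)
    ]
)
pids = [f"P{i}" for i in range(n_patients) for _ in range(patches_each)]

cfg = DeepConvSurvConfig(epochs=5, learning_rate=1e-3, seed=1)
net = train_tissue_extractor(patches, pids, surv, cfg)
feats = net.features(patches[:patches_each])  # one patient's TUM patches
print("per-patch feature shape:", feats.shape)  # (6, 32)

# slide-level: 6 TUM patches out of 20 sampled non-background patches
tum_vec = aggregate_tissue(feats, n_tissue=6, n_total=20)
vectors = {TissueClass.TUM: tum_vec}
for t in (TissueClass.LYM, TissueClass.STR, TissueClass.MUC):
    vectors[t] = np.zeros(32)  # tissues absent from this slide
histo = concat_histo(vectors)
print("histopathological vector width:", histo.shape[0])  # 4 x 32 = 128
print("TUM block weight = 6/20; first values:", np.round(histo[:4], 4))
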