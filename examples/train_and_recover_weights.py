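"""Train the two-range model on a synthetic task with known ground truth.

Labels are 1.0 * c1 + 0.2 * c2 + noise, where c1/c2 count the contacts in
(2,3] and (3,4] A.  A model restricted to the merged range (2,4] can only
see c1 + c2, so its held-out correlation is capped; the two-slice model
separates the ranges and should approach the noise ceiling.
"""

from agima import ModelConfig, SyntheticTaskSpec, forward, make_labeled_dataset, pearson, train
from agima.pipeline import prepare_dataset

dataset = make_labeled_dataset(
    SyntheticTaskSpec(n_complexes=400, weight_range1=1.0, weight_range2=0.2,
                      noise_sd=0.1, seed=11)
)
for scheme in ("AGIMA_2", "AGIMA_SAM"):
    graphs = prepare_dataset(dataset, scheme=scheme)
    train_set, test_set = graphs[:320], graphs[320:]
    cfg = ModelConfig(scheme=scheme, conv_dim=32, dense_dims=(64, 64),
                      dropout_rate=0.1, epochs=60, batch_size=32,
                      learning_rate=3e-3, seed=3)
    state = train(train_set, test_set, cfg)
    preds = [forward(state, F, N)[0] for F, N, _ in test_set]
    pc = pearson([lbl for _, _, lbl in test_set], preds)
    print(f"{scheme:10s} held-out PC = {pc:.4f}")
# expect ~0.998 for the two-range model vs ~0.84 for the merged range:
# distinguishing strong (short) from weak (long) contacts carries signal
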