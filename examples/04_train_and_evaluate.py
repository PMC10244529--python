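"""Train the full network on synthetic faces and evaluate it.

A deliberately small run (200 train / 40 test images at 48², 5 epochs) so it
finishes in a few minutes on one CPU; larger budgets simply improve the MAE.
Prints the per-epoch losses, the test MAE/RMSE, and the mean-predictor
baseline the model must beat.
"""

import numpy as np

from hmhn import TrainConfig, evaluate, generate_arrays, mae, train_on_arrays
from hmhn.metrics import severity_from_score

xtr, ytr = generate_arrays(200, seed=11, size=48)
xte, yte = generate_arrays(40, seed=12, size=48)

cfg = TrainConfig(epochs=5, batch_size=16, seed=0, image_size=48)
result = train_on_arrays(cfg, xtr, ytr, checkpoint_path="scratch/example.ckpt.npz",
                         verbose=True)

test_mae, test_rmse = evaluate(result.model, xte, yte)
baseline = mae(yte, np.full_like(yte, ytr.mean()))
print(f"\ntest MAE {test_mae:.2f}  RMSE {test_rmse:.2f}  "
      f"(mean-predictor baseline MAE {baseline:.2f})")

preds = result.model.predict_scores(xte[:5])
for t, p in zip(yte[:5], preds):
    band = severity_from_score(np.clip(p, 0, 63)).label
    print(f"  true {t:5.1f}  predicted {p:5.1f}  -> {band}")
print("scores are on the BDI-II scale (0-63); bands follow the clinical cut-offs")
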