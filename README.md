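# hmhn

Estimating depression severity from single facial images with a hybrid
multi-head cross-attention network.

Depression alters facial behaviour in several regions at once — drooping
mouth corners, reduced smile, drooping eyelids, knitted brows — and a single
attention map tends to lock onto one coarse region and miss the rest. This
package implements a regression network for the Beck Depression Inventory-II
score (BDI-II, 0–63) built around *multiple* cooperating attention stages:

- **GWA** (grid-wise attention): the 224×224×3 face is split into a 3×3
  grid; per grid cell and channel a scaled dot-product attention matrix
  `softmax(q·kᵀ/√d_k)` is applied to the cell's features and pooled to a
  scalar weight that re-weights the image, injecting long-range spatial
  structure before any deep features exist.
- **DFF** (deep feature fusion): two independently parameterised transforms
  of the raw and re-weighted images are summed, fused, and passed through a
  ResNet-18 trunk with its pooling/flatten/FC head removed (512×7×7 output).
- **MAB** (multi-head cross attention): k = 4 parallel heads, each a spatial
  attention unit (1×1 reduce + separable 3×3/1×3/3×1 convolutions + sigmoid
  gate) followed by a channel attention unit (two-linear bottleneck gate).
- **AFB** (attention fusion): head outputs are merged and regressed to the
  score; training minimises `L_sum = L_att + L_mse`, where the *partition
  loss* `L_att = (1/NC) Σ_ij log(1 + k/(σ²_ij + ε))` penalises low variance
  across heads so that different heads attend to different facial regions.

Predicted scores map onto the clinical severity bands 0–13 none/minimal,
14–19 mild, 20–28 moderate, 29–63 severe; evaluation uses MAE and RMSE.

Because the clinical video corpora for this task are access-restricted, the
package includes a seeded synthetic face generator whose mouth curvature,
eye openness and brow angle vary monotonically with a latent severity score
— every component is testable end to end without restricted data. The whole
network runs on a compact numpy autograd engine included in the package
(`hmhn.nn`), so there is no deep-learning framework dependency.

## Worked example

```python
import numpy as np
from hmhn import TrainConfig, evaluate, generate_arrays, mae, train_on_arrays

xtr, ytr = generate_arrays(200, seed=11, size=48)   # synthetic faces + scores
xte, yte = generate_arrays(40,  seed=12, size=48)
cfg = TrainConfig(epochs=5, batch_size=16, seed=0, image_size=48)
result = train_on_arrays(cfg, xtr, ytr, verbose=True)
test_mae, test_rmse = evaluate(result.model, xte, yte)
print(test_mae, test_rmse, mae(yte, np.full_like(yte, ytr.mean())))
```

Output of `python examples/04_train_and_evaluate.py` (same run):

```
epoch   1  L_mse   590.433  L_att  3.5143  L_sum   593.947  dev MAE 11.539  RMSE 14.938
epoch   2  L_mse   301.696  L_att  3.5925  L_sum   305.288  dev MAE 12.659  RMSE 14.298
epoch   3  L_mse   117.815  L_att  3.5409  L_sum   121.356  dev MAE  7.634  RMSE  9.461
epoch   4  L_mse    32.026  L_att  3.3482  L_sum    35.374  dev MAE  5.579  RMSE  6.496
epoch   5  L_mse    17.005  L_att  3.0326  L_sum    20.038  dev MAE  3.256  RMSE  3.977

test MAE 4.42  RMSE 5.32  (mean-predictor baseline MAE 13.46)
```

The per-epoch lines show the regression loss, the partition loss and their
sum falling as the network learns; after five epochs the test MAE is a third
of the mean-predictor baseline, i.e. the model reads the geometric severity
cues. Longer budgets narrow it further (10 epochs on 400 images reaches test
MAE ≈ 2.5).

Other walkthroughs in `examples/`: the synthetic generator and its monotone
severity signal (`01`), the grid-attention stage step by step (`02`), the
parameter budgets of the kernel configurations (`03`), attention heatmap
export (`05`).

There is also a thin CLI:

```bash
hmhn synth --n 200 --seed 1 --out faces/
hmhn train --manifest faces/manifest.csv --checkpoint model.npz --image-size 96 --epochs 5
hmhn eval  --manifest faces/manifest.csv --checkpoint model.npz --json
hmhn predict --checkpoint model.npz faces/test_00000.png
hmhn attention --image faces/test_00000.png --checkpoint model.npz --out heatmaps/
```

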