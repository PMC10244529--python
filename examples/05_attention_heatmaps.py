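"""Export per-head spatial attention heatmaps for one face.

Each of the four cross-attention heads produces its own spatial gate; the
partition loss trains them to focus on different facial regions.  Untrained
gates are near-uniform — train a model first (example 04) for structure.
"""

from hmhn import build_model
from hmhn.synthetic import generate_sample
from hmhn.viz import attention_gates, save_heatmaps

img, _ = generate_sample(seed=5, score=40.0, size=96)
model = build_model(seed=0)

gates = attention_gates(model, img)
print(f"{gates.shape[0]} heads, gate maps {gates.shape[1:]} (normalised to [0,1])")
for i, g in enumerate(gates):
    print(f"  head {i}: gate mass centre row={g.mean(axis=1).argmax()}, "
          f"col={g.mean(axis=0).argmax()}")

paths = save_heatmaps(model, img, "scratch/heatmaps")
print("overlay PNGs written:")
for p in paths:
    print(f"  {p}")
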