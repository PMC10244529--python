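"""Generate synthetic severity-labelled faces and inspect the encoded signal.

Renders a small dataset, prints the score distribution, and shows that the
mouth-region intensity moves monotonically with the latent BDI-II score —
the geometric cue the network is supposed to pick up.
"""

import numpy as np
from scipy.stats import spearmanr

from hmhn import generate_dataset, generate_sample
from hmhn.synthetic import mouth_region_intensity

manifest = generate_dataset(n=30, seed=7, out_dir="scratch/example_faces", size=96)
scores = [round(s, 1) for _, s, _ in manifest.rows[:8]]
print(f"wrote {len(manifest.rows)} PNGs to {manifest.root}")
print(f"first training scores: {scores}")
print("(right-skewed: most synthetic subjects score in the low BDI-II range)")

grid = np.arange(64.0)
signal = [mouth_region_intensity(generate_sample(0, s, jitter=False, noise=False)[0])
          for s in grid]
rho = spearmanr(grid, signal).statistic
print(f"Spearman rho(score, mouth-region intensity) = {rho:.3f}")
print("|rho| near 1 means the severity signal survives rasterisation,")
print("so a vision model can in principle regress the score from pixels.")
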