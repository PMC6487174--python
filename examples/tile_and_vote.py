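"""Patch tiling at the micrograph geometry plus majority voting.

A 1388x1040 image tiles into the 21x16 grid of 336 nonoverlapping 64x64
patches (right/bottom remainders dropped).  Majority voting then turns a
set of patch labels into one image label; the demo vote shows that a
60/40 split of patch opinions still yields a confident image call.
"""

import numpy as np

from multispace import SynthConfig, generate_dataset, majority_vote, tile_image

cfg = SynthConfig(image_size=(1388, 1040), n_per_class=1, seed=3)
images, labels, _ = generate_dataset(cfg)
grid = tile_image(images[0], 64)
print(f"grid: {grid.n_cols} cols x {grid.n_rows} rows = {len(grid)} patches")
print(f"first origins: {grid.origins[:3].tolist()}  (row_px, col_px)")

# 202 patches say class 0, 134 say class 2: the image votes class 0.
patch_labels = np.array([0] * 202 + [2] * 134)
print(f"majority vote over {len(patch_labels)} patch labels "
      f"(202 x class0, 134 x class2): image label = {majority_vote(patch_labels)}")
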