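"""Adaptive spatial block-size selection from autocorrelation decay.

The block size M is the smallest pixel lag at which the band-averaged
row/column autocorrelation falls into the [0.9, 0.95] window: blocks of
that size are still internally coherent, hence sparse under a 2-D DCT.
"""

import numpy as np

from pssahcs import HyperspectralCube, ar1_field, select_block_size
from pssahcs.blocking import mean_lag_correlations

rng = np.random.default_rng(0)
bands = [
    np.clip(np.round(2048 + 400 * ar1_field(256, 256, 0.98, rng)), 0, 4095)
    for _ in range(8)
]
cube = HyperspectralCube(np.stack(bands, 2).astype(np.uint16), bit_depth=12)

vals = mean_lag_correlations(cube, list(range(8)), lag_max=8)
for lag, v in enumerate(vals, start=1):
    marker = " <- in [0.90, 0.95]" if 0.9 <= v <= 0.95 else ""
    print(f"lag {lag}: mean row/col autocorrelation {v:.4f}{marker}")

plan = select_block_size(cube, lag_max=8)
print(f"\nselected block size M = {plan.block_size}")
print(f"tiling: {plan.n_blocks} blocks of {plan.block_size}x{plan.block_size} "
      f"(padding {plan.pad_rows} rows, {plan.pad_cols} cols)")
print("the first lag inside the window becomes the codec's block size;")
print("the pipeline additionally floors it at block_min (default 32), the")
print("smallest block on which the StOMP stage threshold is meaningful.")
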