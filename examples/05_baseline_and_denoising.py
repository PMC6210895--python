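"""Prediction advantage over plain blocked CS, and absorption-band
denoising.

The blocked-CS baseline senses every band independently at the same total
bit budget. The full codec concentrates budget on each group's key band
and predicts the rest, so the whole group rides the key band's higher
fidelity — and the unsparse noise of absorption bands is largely not
reconstructed, which denoises them relative to the clean scene.
"""

import numpy as np

from pssahcs import (
    CodecConfig,
    baseline_blocked_cs,
    compress,
    decompress,
    generate_cube,
    per_band_psnr,
    psnr,
    tea_like_spec,
)

cube, truth = generate_cube(tea_like_spec(seed=0))
cfg = CodecConfig(bpp=0.25, kmeans_seed=0, matrix_seed=0)

recon = decompress(compress(cube, cfg))
base, bpkg = baseline_blocked_cs(cube, cfg)
print(f"PSSAHCS  PSNR {psnr(cube, recon):.2f} dB")
print(f"baseline PSNR {psnr(cube, base):.2f} dB (same realized rate "
      f"{bpkg.realized_bpp():.4f})")

noisy = [z for z, _ in truth.noisy_bands]
rec_vs_clean = per_band_psnr(truth.clean_cube, recon)[noisy]
inp_vs_clean = per_band_psnr(truth.clean_cube, cube)[noisy]
print(f"\nabsorption bands {noisy} against the clean ground truth:")
print(f"  noisy input:    {np.round(inp_vs_clean, 1)} dB")
print(f"  reconstruction: {np.round(rec_vs_clean, 1)} dB")
print("the reconstruction sits closer to the clean scene than the input")
print("does: the codec has removed part of the absorption-band noise.")
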