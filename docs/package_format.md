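# The `.pssahcs` package format

A compressed cube is a single file: a NumPy `.npz` archive (a standard
zip of `.npy` members) whose `meta` member is a UTF-8 JSON document. The
package is fully self-contained — decoding uses nothing but the file —
and byte-reproducible for fixed inputs and seeds.

## Archive members

| member         | dtype            | shape              | content |
| -------------- | ---------------- | ------------------ | ------- |
| `meta`         | uint8            | (len,)             | UTF-8 JSON metadata (below) |
| `measurements` | uint16 or uint32 | (c, n_blocks, m_max) | quantized measurement codes; band `z` uses columns `0..meas_counts[z]` |
| `meas_counts`  | int32            | (c,)               | measurements per block for each band |
| `q_lo`         | float64          | (c,)               | per-band quantizer minimum |
| `q_hi`         | float64          | (c,)               | per-band quantizer maximum |
| `wavelengths`  | float64          | (c,)               | optional; band centre wavelengths in nm |

The code dtype is uint16 for quantizer depths up to 16 bits, uint32
beyond. Dequantization of band `z` is
`q_lo[z] + codes / (2**quant_bits − 1) * (q_hi[z] − q_lo[z])`.

## JSON metadata (`meta`)

```json
{
  "magic": "pssahcs",
  "version": 1,
  "config": { "... every CodecConfig field, including bpp, quant_bits,",
              "budget_split, stomp_* and the kmeans/matrix seeds ..." },
  "block": { "block_size": 32, "rows": 128, "cols": 256,
             "pad_rows": 0, "pad_cols": 0 },
  "grouping": { "groups": [[0, 1, "..."]], "key_bands": [2, 20, 32],
                "k": 3, "seed": 1 },
  "predictors": { "0": { "m": 0.98, "n": 31.2, "key_band": 2 }, "...": {} },
  "original_shape": [128, 256, 40],
  "bit_depth": 12,
  "side_info": { "selected_block_size": 3, "m_key": 614, "m_res": 307,
                 "measurement_bits": 3929856, "side_info_bits": 9984,
                 "realized_bpp": 0.2499 }
}
```

Invariants checked on load: magic and version match; every band is
either a key band or has exactly one predictor entry; the measurement
array holds one vector per (band, block) cell. Violations, truncation,
or a non-zip file raise `PackageFormatError`.

The measurement matrix is never stored: the decoder regenerates it from
`config.matrix_seed` and the block size, which keeps the package small
and decoding exact.
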