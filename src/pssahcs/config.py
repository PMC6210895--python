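"""Codec configuration: every tunable and seed the codec consumes.

The rate knob ``bpp`` is the fraction of the native cube bits the stored
measurements may occupy: each M x M block of N = M^2 pixels receives

    m_meas = round(bpp * N * n_bits / quant_bits)

measurements of quant_bits each, so the stored measurement bits equal
bpp * N * n_bits per block exactly. With quant_bits equal to the native
depth the operating point is also the per-block sampling fraction m/N;
the default 8-bit quantizer instead trades precision for n_bits/8 times
more measurements at the same budget (its noise floor sits far above the
solver's reconstruction error, so the extra measurements win). Prediction
side information (two floats per non-key band) and seeds are excluded
from the rate figure and reported separately.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

__all__ = ["CodecConfig"]


@dataclass
class CodecConfig:
    # rate control
    bpp: float = 0.25
    quant_bits: int = 8
    budget_split: float = 2.0   # key-band / non-key-band measurement ratio

    # spatial blocking
    lag_max: int = 32
    corr_lo: float = 0.9
    corr_hi: float = 0.95
    band_sample_count: int = 8
    block_min: int = 32
    block_max: int = 64

    # spectral grouping
    k: int | str = "auto"
    kmeans_seed: int = 0
    contiguity: bool = True
    adjacent_corr_threshold: float = 0.9
    lmlsd_intervals: int = 10
    lmlsd_block_size: int = 8   # fine tiling for local noise statistics

    # compressive sensing
    matrix_seed: int = 0
    stomp_t: float = 3.0
    stomp_max_stages: int = 10
    stomp_tol: float = 1e-6

    def __post_init__(self):
        if self.bpp <= 0:
            raise ValueError("bpp must be positive")
        if not 0 < self.budget_split:
            raise ValueError("budget_split must be positive")
        if self.block_min < 1 or self.block_max < self.block_min:
            raise ValueError("need 1 <= block_min <= block_max")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CodecConfig":
        return cls(**d)
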