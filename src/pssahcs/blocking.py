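"""Adaptive spatial blocking.

Hyperspectral scenes are spatially autocorrelated: neighbouring pixels in a
band image are similar. The discrete, normalized spatial autocorrelation
eta(dx, dy, z) of band z measures that similarity at a pixel offset
(dx, dy). The codec's square block size M is chosen adaptively as the
smallest lag at which the band-averaged row/column autocorrelation falls
into a target window (default [0.9, 0.95]): blocks of that size are still
internally coherent (hence sparse under a 2-D DCT) without being larger
than the correlation length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import HyperspectralCube
from .errors import ConstantBandError

__all__ = ["BlockPlan", "spatial_autocorrelation", "select_block_size", "make_plan"]


@dataclass(frozen=True)
class BlockPlan:
    """Tiling of an ``rows x cols`` grid by disjoint ``M x M`` blocks.

    The grid is reflect-padded on the right/bottom so both dimensions become
    multiples of M; the padding amounts are recorded so reconstruction can
    strip them.
    """

    block_size: int
    rows: int
    cols: int
    pad_rows: int
    pad_cols: int
    blocks: tuple = field(default=(), compare=False)

    def __post_init__(self):
        if self.block_size < 1:
            raise ValueError("block size must be >= 1")
        pr, pc = self.padded_rows, self.padded_cols
        tiles = tuple(
            (r, c)
            for r in range(0, pr, self.block_size)
            for c in range(0, pc, self.block_size)
        )
        object.__setattr__(self, "blocks", tiles)

    @property
    def padded_rows(self) -> int:
        return self.rows + self.pad_rows

    @property
    def padded_cols(self) -> int:
        return self.cols + self.pad_cols

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_pixels(self) -> int:
        """Pixels per block, N = M**2."""
        return self.block_size * self.block_size

    def pad(self, image: np.ndarray) -> np.ndarray:
        """Reflect-pad a band image to the padded grid."""
        if image.shape != (self.rows, self.cols):
            raise ValueError(
                f"image shape {image.shape} != plan shape {(self.rows, self.cols)}"
            )
        if self.pad_rows == 0 and self.pad_cols == 0:
            return np.asarray(image, dtype=np.float64)
        mode = "reflect" if min(self.rows, self.cols) > 1 else "edge"
        return np.pad(
            np.asarray(image, dtype=np.float64),
            ((0, self.pad_rows), (0, self.pad_cols)),
            mode=mode,
        )

    def unpad(self, image: np.ndarray) -> np.ndarray:
        return image[: self.rows, : self.cols]

    def to_blocks(self, image: np.ndarray) -> np.ndarray:
        """Split a (possibly unpadded) band image into ``(n_blocks, M, M)``."""
        padded = self.pad(image) if image.shape == (self.rows, self.cols) else image
        M = self.block_size
        out = np.empty((self.n_blocks, M, M), dtype=np.float64)
        for i, (r, c) in enumerate(self.blocks):
            out[i] = padded[r : r + M, c : c + M]
        return out

    def from_blocks(self, blocks: np.ndarray) -> np.ndarray:
        """Reassemble blocks into the padded image (inverse of to_blocks)."""
        M = self.block_size
        img = np.empty((self.padded_rows, self.padded_cols), dtype=np.float64)
        for i, (r, c) in enumerate(self.blocks):
            img[r : r + M, c : c + M] = blocks[i]
        return img


def _autocorr_image(image: np.ndarray, dx: int, dy: int) -> float:
    """Normalized autocorrelation of a single band image at lag (dx, dy).

    Both sums run over pixel pairs where both (x, y) and (x+dx, y+dy) lie
    inside the image; the denominator is the unshifted sum of squares over
    those same pixels, with deviations taken from the whole-band mean.
    The result is clipped to [-1, 1].
    """
    a, b = image.shape
    if not (0 <= dx < a and 0 <= dy < b):
        raise ValueError(f"lag ({dx}, {dy}) out of range for a {a}x{b} image")
    f = np.asarray(image, dtype=np.float64)
    fbar = f.mean()
    base = f[: a - dx, : b - dy] - fbar
    shifted = f[dx:, dy:] - fbar
    denom = np.sum(base * base)
    if denom == 0.0:
        raise ConstantBandError(
            "autocorrelation undefined: band is constant over the overlap region"
        )
    eta = float(np.sum(base * shifted) / denom)
    return float(np.clip(eta, -1.0, 1.0))


def spatial_autocorrelation(
    cube: HyperspectralCube, band: int, dx: int, dy: int
) -> float:
    """Spatial autocorrelation eta(dx, dy, z) of band ``band``."""
    return _autocorr_image(cube.band_float(band), dx, dy)


def _default_band_sample(bands: int, count: int = 8) -> list[int]:
    count = min(count, bands)
    return sorted({int(round(i)) for i in np.linspace(0, bands - 1, count)})


def mean_lag_correlations(
    cube: HyperspectralCube, band_sample: list[int], lag_max: int
) -> np.ndarray:
    """Mean over sampled bands of (row + column) autocorrelation at each lag.

    Entry d-1 holds the mean of (eta(d, 0, z) + eta(0, d, z)) / 2 over the
    sampled bands, for d = 1..lag_max.
    """
    vals = np.empty(lag_max)
    images = [cube.band_float(z) for z in band_sample]
    for d in range(1, lag_max + 1):
        acc = 0.0
        for img in images:
            acc += 0.5 * (_autocorr_image(img, d, 0) + _autocorr_image(img, 0, d))
        vals[d - 1] = acc / len(images)
    return vals


def make_plan(rows: int, cols: int, block_size: int) -> BlockPlan:
    """Build a BlockPlan for a grid, computing the reflect-padding amounts."""
    M = min(block_size, rows, cols)
    pad_r = (-rows) % M
    pad_c = (-cols) % M
    return BlockPlan(block_size=M, rows=rows, cols=cols, pad_rows=pad_r, pad_cols=pad_c)


def select_block_size(
    cube: HyperspectralCube,
    band_sample: list[int] | None = None,
    lag_max: int = 32,
    lo: float = 0.9,
    hi: float = 0.95,
    fallback_min: int = 8,
) -> BlockPlan:
    """Adaptively choose the square block size M from spatial correlation.

    For each lag d in 1..lag_max the row and column autocorrelations are
    averaged over a sample of bands; M is the smallest lag whose mean lies
    in [lo, hi]. When no lag qualifies: if the correlation stays above hi
    everywhere, M = lag_max (the scene is smoother than the probe range);
    if it is already below lo at lag 1, M = fallback_min (the scene is
    noise-like and a minimum practical block is used); otherwise the last
    lag still above hi is taken.
    """
    if lag_max < 1:
        raise ValueError("lag_max must be >= 1")
    if band_sample is None:
        band_sample = _default_band_sample(cube.bands)
    if not band_sample:
        raise ValueError("band_sample must be non-empty")
    lag_max = min(lag_max, cube.rows - 1, cube.cols - 1)
    if lag_max < 1:
        raise ValueError("cube too small for any spatial lag")

    vals = mean_lag_correlations(cube, band_sample, lag_max)
    in_band = np.nonzero((vals >= lo) & (vals <= hi))[0]
    if in_band.size:
        M = int(in_band[0]) + 1
    elif np.all(vals > hi):
        M = lag_max
    elif vals[0] < lo:
        M = fallback_min
    else:
        # correlation jumps from above hi to below lo: take the last lag
        # still above the window
        above = np.nonzero(vals > hi)[0]
        M = int(above[-1]) + 1
    return make_plan(cube.rows, cube.cols, M)
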