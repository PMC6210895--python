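"""Per-block compressive sensing: Gaussian measurements, 2-D DCT sparse
basis, and stagewise orthogonal matching pursuit (StOMP) recovery.

A block of N = M*M pixels, raster-vectorized row-major into x, is sampled
as y = Phi x with an i.i.d. Gaussian matrix Phi of shape (m, N), entries
N(0, 1/m) drawn from a recorded seed (so the matrix is never transmitted —
the decoder regenerates it). The sparse basis Psi is the separable
orthonormal 2-D DCT synthesis operator: x = Psi theta where theta are the
block's 2-D DCT coefficients. Recovery solves y ~= (Phi Psi) theta with
StOMP, which at each stage selects every atom whose matched-filter
amplitude exceeds t times the formal noise level ||r||/sqrt(m), then
re-solves least squares on the accumulated support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.linalg

__all__ = [
    "SensingOperator",
    "MeasurementVector",
    "make_operator",
    "sense",
    "stomp",
    "reconstruct_block",
    "quantize",
    "dequantize",
]


def dct2_synthesis_matrix(block_size: int) -> np.ndarray:
    """Orthonormal 2-D DCT synthesis matrix Psi of shape (N, N), N = M*M.

    With C the orthonormal 1-D DCT-II analysis matrix, the 2-D analysis of a
    block B is C B C^T, so the synthesis of row-major-vectorized
    coefficients is kron(C^T, C^T).
    """
    C = scipy.fft.dct(np.eye(block_size), axis=0, norm="ortho")
    return np.kron(C.T, C.T)


@dataclass(frozen=True)
class SensingOperator:
    """Seeded Gaussian measurement matrix + DCT basis for one block size."""

    phi: np.ndarray = field(repr=False)
    psi: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)
    block_size: int
    m_meas: int
    seed: int

    @property
    def n_pixels(self) -> int:
        return self.block_size * self.block_size


@dataclass
class MeasurementVector:
    """One block's measurement vector y = Phi x."""

    y: np.ndarray
    band: int = -1
    block: int = -1


def make_operator(block_size: int, m_meas: int, seed: int) -> SensingOperator:
    """Build the sensing operator for ``block_size`` x ``block_size`` blocks.

    Phi entries are i.i.d. N(0, 1/m_meas) from ``seed``; identical inputs
    give a bit-identical operator.
    """
    N = block_size * block_size
    if not 1 <= m_meas <= N:
        raise ValueError(f"m_meas must be in [1, {N}], got {m_meas}")
    rng = np.random.default_rng(seed)
    phi = rng.normal(0.0, 1.0 / np.sqrt(m_meas), size=(m_meas, N))
    psi = dct2_synthesis_matrix(block_size)
    return SensingOperator(
        phi=phi, psi=psi, A=phi @ psi, block_size=block_size, m_meas=m_meas, seed=seed
    )


def sense(block_pixels: np.ndarray, op: SensingOperator,
          band: int = -1, block: int = -1) -> MeasurementVector:
    """Measure a block: y = Phi x for the row-major vectorized block."""
    x = np.asarray(block_pixels, dtype=np.float64).reshape(-1)
    if x.size != op.n_pixels:
        raise ValueError(f"block has {x.size} pixels, operator expects {op.n_pixels}")
    return MeasurementVector(y=op.phi @ x, band=band, block=block)


def stomp(
    y: np.ndarray,
    A: np.ndarray,
    t: float = 2.5,
    max_stages: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Stagewise orthogonal matching pursuit.

    Stage s: matched filter c = A^T r; formal noise sigma = ||r||/sqrt(m);
    all atoms with |c_j| > t*sigma join the running support (capped at m,
    keeping the largest |c|); least squares of y on the support columns
    updates the residual. Stops when ||r|| <= tol*||y||, no new atom is
    selected, or ``max_stages`` stages have run. Returns the length-N
    coefficient vector, zero off-support; a rank-deficient support solve
    returns the minimum-norm solution.
    """
    if t <= 0:
        raise ValueError("threshold multiplier t must be positive")
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    m, N = A.shape
    if y.size != m:
        raise ValueError(f"y has {y.size} entries, A has {m} rows")

    x = np.zeros(N)
    ynorm = np.linalg.norm(y)
    if ynorm == 0.0:
        return x

    support = np.zeros(N, dtype=bool)
    r = y.copy()
    coef = None
    for _ in range(max_stages):
        rnorm = np.linalg.norm(r)
        if rnorm <= tol * ynorm:
            break
        c = A.T @ r
        sigma = rnorm / np.sqrt(m)
        selected = np.abs(c) > t * sigma
        new = selected & ~support
        if not np.any(new):
            break
        cand = support | selected
        if cand.sum() > m:
            # keep the m strongest candidates by matched-filter amplitude
            # (existing support scored by current coefficient magnitude)
            score = np.abs(c)
            if coef is not None:
                idx_old = np.nonzero(support)[0]
                score[idx_old] = np.maximum(score[idx_old], np.abs(coef))
            score[~cand] = -np.inf
            keep = np.argsort(score)[::-1][:m]
            cand = np.zeros(N, dtype=bool)
            cand[keep] = True
        support = cand
        cols = np.nonzero(support)[0]
        coef, *_ = scipy.linalg.lstsq(A[:, cols], y, lapack_driver="gelsd")
        r = y - A[:, cols] @ coef

    if coef is not None:
        x[np.nonzero(support)[0]] = coef
    return x


def reconstruct_block(
    mv: MeasurementVector | np.ndarray,
    op: SensingOperator,
    t: float = 2.5,
    max_stages: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """StOMP-recover DCT coefficients from y, synthesize, return M x M pixels."""
    y = mv.y if isinstance(mv, MeasurementVector) else np.asarray(mv)
    theta = stomp(y, op.A, t=t, max_stages=max_stages, tol=tol)
    pixels = op.psi @ theta
    M = op.block_size
    return pixels.reshape(M, M)


# ---------------------------------------------------------------------------
# Uniform scalar quantization of measurement values
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, q_bits: int = 12) -> tuple[np.ndarray, float, float]:
    """Uniform scalar quantization to ``q_bits`` levels over [min, max].

    Returns (codes, lo, hi); codes are unsigned integers. A constant input
    maps to all-zero codes with lo == hi.
    """
    if not 1 <= q_bits <= 32:
        raise ValueError("q_bits must be in [1, 32]")
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    levels = (1 << q_bits) - 1
    dtype = np.uint16 if q_bits <= 16 else np.uint32
    if hi == lo:
        return np.zeros(v.shape, dtype=dtype), lo, hi
    codes = np.round((v - lo) / (hi - lo) * levels)
    return codes.astype(dtype), lo, hi


def dequantize(codes: np.ndarray, lo: float, hi: float, q_bits: int = 12) -> np.ndarray:
    """Invert :func:`quantize` up to quantization error."""
    if hi == lo:
        return np.full(codes.shape, lo, dtype=np.float64)
    levels = (1 << q_bits) - 1
    return lo + codes.astype(np.float64) / levels * (hi - lo)
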