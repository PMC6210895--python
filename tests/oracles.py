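"""Independent brute-force oracles: literal double/triple-loop
transcriptions of the codec's defining formulas, kept deliberately naive
and separate from the implementation paths they check."""

from __future__ import annotations

import math

import numpy as np


def eta_oracle(f: np.ndarray, dx: int, dy: int) -> float:
    """Spatial autocorrelation at lag (dx, dy): explicit double loop over
    in-bounds pixel pairs, deviations from the whole-band mean, denominator
    from the unshifted samples of those same pairs."""
    a, b = f.shape
    fbar = f.mean()
    num = 0.0
    den = 0.0
    for x in range(a - dx):
        for y in range(b - dy):
            num += (f[x, y] - fbar) * (f[x + dx, y + dy] - fbar)
            den += (f[x, y] - fbar) ** 2
    return max(-1.0, min(1.0, num / den))


def band_distance_oracle(f1: np.ndarray, f2: np.ndarray) -> float:
    """Euclidean band distance: explicit double-loop sum of squares."""
    a, b = f1.shape
    s = 0.0
    for x in range(a):
        for y in range(b):
            s += (f1[x, y] - f2[x, y]) ** 2
    return math.sqrt(s)


def lmlsd_oracle(blocks: list[np.ndarray], n_intervals: int):
    """LMLSD score from a list of sub-block images: per-block mean and
    sample standard deviation (divisor a*b - 1), equal-width histogram of
    the stds, modal interval (ties to the lower), and
    R = 20 log10(M_mean / D_mean)."""
    means, stds = [], []
    for blk in blocks:
        a, b = blk.shape
        m = 0.0
        for i in range(a):
            for j in range(b):
                m += blk[i, j]
        m /= a * b
        d = 0.0
        for i in range(a):
            for j in range(b):
                d += (blk[i, j] - m) ** 2
        d = math.sqrt(d / (a * b - 1))
        means.append(m)
        stds.append(d)

    d_lo, d_hi = min(stds), max(stds)
    if d_hi == d_lo:
        members = list(range(len(blocks)))
    else:
        width = (d_hi - d_lo) / n_intervals
        counts = [0] * n_intervals
        assign = []
        for d in stds:
            idx = min(int((d - d_lo) / width), n_intervals - 1)
            assign.append(idx)
            counts[idx] += 1
        modal = counts.index(max(counts))  # first max: lower interval
        members = [i for i, idx in enumerate(assign) if idx == modal]

    m_mean = sum(means[i] for i in members) / len(members)
    d_mean = sum(stds[i] for i in members) / len(members)
    r = 20.0 * math.log10(m_mean / d_mean)
    return r, m_mean, d_mean


def affine_fit_oracle(ref: np.ndarray, target: np.ndarray):
    """Two-parameter least squares via an independent design-matrix solve."""
    X = np.column_stack([ref.reshape(-1), np.ones(ref.size)])
    coef, *_ = np.linalg.lstsq(X, target.reshape(-1), rcond=None)
    return float(coef[0]), float(coef[1])


def mse_oracle(f1: np.ndarray, f2: np.ndarray) -> float:
    """3-D mean squared error: explicit triple loop."""
    a, b, c = f1.shape
    s = 0.0
    for x in range(a):
        for y in range(b):
            for z in range(c):
                s += abs(float(f1[x, y, z]) - float(f2[x, y, z])) ** 2
    return s / (a * b * c)


def psnr_oracle(f1: np.ndarray, f2: np.ndarray, n_bits: int) -> float:
    mse = mse_oracle(f1, f2)
    return 10.0 * math.log10(((2 ** n_bits - 1) ** 2) / mse)


def zeta_oracle(f1: np.ndarray, f2: np.ndarray) -> float:
    """Spectral correlation: explicit double loops for all three sums."""
    a, b = f1.shape
    m1 = f1.mean()
    m2 = f2.mean()
    num = s1 = s2 = 0.0
    for x in range(a):
        for y in range(b):
            num += (f1[x, y] - m1) * (f2[x, y] - m2)
            s1 += (f1[x, y] - m1) ** 2
            s2 += (f2[x, y] - m2) ** 2
    return num / math.sqrt(s1 * s2)


def exhaustive_1sparse(y: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Best single-atom least-squares fit by exhaustive search."""
    best_j, best_c, best_r = 0, 0.0, np.inf
    for j in range(A.shape[1]):
        aj = A[:, j]
        c = float(aj @ y) / float(aj @ aj)
        r = float(np.linalg.norm(y - c * aj))
        if r < best_r:
            best_j, best_c, best_r = j, c, r
    x = np.zeros(A.shape[1])
    x[best_j] = best_c
    return x


def lstsq_on_support(y: np.ndarray, A: np.ndarray, support) -> np.ndarray:
    """Least squares restricted to the given true support."""
    cols = sorted(support)
    coef, *_ = np.linalg.lstsq(A[:, cols], y, rcond=None)
    x = np.zeros(A.shape[1])
    x[cols] = coef
    return x
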