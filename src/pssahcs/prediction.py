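"""Interband linear prediction.

Within a spectral group every non-key band g is modelled as an affine
function of the key (reference) band R:

    f_g(x, y) ~= m * f_R(x, y) + n

The coefficients minimize the mean squared prediction error and have the
closed form

    m = (E[f_R f_g] - E[f_R] E[f_g]) / (E[f_R^2] - E[f_R]^2),
    n = E[f_g] - m * E[f_R],

i.e. ordinary least squares on the pixel pairs. Only the residual
f_g - (m f_R + n) is compressively sampled; the decoder re-adds the
prediction from its own reconstructed key band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConstantBandError

__all__ = ["PredictorPair", "fit_predictor", "predict", "residual", "reconstruct_band"]


@dataclass(frozen=True)
class PredictorPair:
    """Affine prediction coefficients for one non-key band."""

    m: float
    n: float
    band: int = -1
    key_band: int = -1

    def __post_init__(self):
        if not (np.isfinite(self.m) and np.isfinite(self.n)):
            raise ValueError(f"non-finite prediction coefficients ({self.m}, {self.n})")


def fit_predictor(
    ref_image: np.ndarray,
    target_image: np.ndarray,
    band: int = -1,
    key_band: int = -1,
) -> PredictorPair:
    """Least-squares fit of ``target ~= m * ref + n`` over all pixels.

    Raises :class:`ConstantBandError` when the reference image is constant
    (zero variance denominator); callers fall back to ``m=0,
    n=mean(target)`` and record that in the package.
    """
    fr = np.asarray(ref_image, dtype=np.float64)
    fg = np.asarray(target_image, dtype=np.float64)
    if fr.shape != fg.shape:
        raise ValueError(f"shape mismatch: {fr.shape} vs {fg.shape}")

    u_r = fr.mean()
    u_g = fg.mean()
    cross = float(np.mean(fr * fg))          # E[f_R f_g]
    second = float(np.mean(fr * fr))         # E[f_R^2]
    denom = second - u_r * u_r
    if denom <= 0.0:
        raise ConstantBandError("constant reference image: predictor undefined")
    m = (cross - u_r * u_g) / denom
    n = u_g - m * u_r
    return PredictorPair(m=float(m), n=float(n), band=band, key_band=key_band)


def predict(ref_image: np.ndarray, pair: PredictorPair) -> np.ndarray:
    """Elementwise affine prediction ``m * ref + n`` (float, no rounding)."""
    return pair.m * np.asarray(ref_image, dtype=np.float64) + pair.n


def residual(target_image: np.ndarray, predicted_image: np.ndarray) -> np.ndarray:
    """Signed prediction residual ``target - predicted`` (may be negative)."""
    t = np.asarray(target_image, dtype=np.float64)
    p = np.asarray(predicted_image, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return t - p


def reconstruct_band(
    predicted_image: np.ndarray, recon_residual: np.ndarray
) -> np.ndarray:
    """Undo the residual: ``predicted + recon_residual`` (float).

    Clipping to the DN range and integer rounding happen once, at final
    cube output, not here.
    """
    p = np.asarray(predicted_image, dtype=np.float64)
    r = np.asarray(recon_residual, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    return p + r
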