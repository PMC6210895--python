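"""Quality evaluation: PSNR, spatial correlation curves, spectral correlation.

PSNR uses the 3-D mean squared error over all voxels against the peak DN
value (2**n - 1)**2; per-band PSNR is also reported. Spatial fidelity is
judged by row/column autocorrelation curves of selected bands; spectral
fidelity by the Pearson correlation zeta(z1, z2) between band images and
by mean spectral profiles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .blocking import _autocorr_image
from .cube import HyperspectralCube
from .errors import ConstantBandError

__all__ = [
    "psnr",
    "per_band_psnr",
    "spectral_correlation",
    "correlation_curves",
    "evaluate",
    "EvaluationReport",
]

#: Showcase wavelengths (nm) used when the cube carries a wavelength axis:
#: a blue band, a red band, and a NIR band near typical water-absorption
#: noise.
DEFAULT_EVAL_WAVELENGTHS = (440.0, 620.0, 980.0)


def _check_same_shape(orig: HyperspectralCube, recon: HyperspectralCube) -> None:
    if orig.shape != recon.shape:
        raise ValueError(f"shape mismatch: {orig.shape} vs {recon.shape}")
    if orig.bit_depth != recon.bit_depth:
        raise ValueError(
            f"bit depth mismatch: {orig.bit_depth} vs {recon.bit_depth}"
        )


def psnr(orig: HyperspectralCube, recon: HyperspectralCube) -> float:
    """Peak signal-to-noise ratio in dB over all voxels.

    MSE is averaged over all a*b*c voxels; the peak is 2**n - 1 for bit
    depth n. Identical cubes have no finite PSNR and return ``math.inf``
    (the "identical" sentinel).
    """
    _check_same_shape(orig, recon)
    diff = orig.data.astype(np.float64) - recon.data.astype(np.float64)
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return math.inf
    peak = float(orig.dn_max)
    return 10.0 * math.log10(peak * peak / mse)


def per_band_psnr(orig: HyperspectralCube, recon: HyperspectralCube) -> np.ndarray:
    """PSNR of each band separately (inf where a band is identical)."""
    _check_same_shape(orig, recon)
    diff = orig.data.astype(np.float64) - recon.data.astype(np.float64)
    mse = np.mean(diff * diff, axis=(0, 1))
    peak2 = float(orig.dn_max) ** 2
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(peak2 / mse)


def spectral_correlation(cube: HyperspectralCube, z1: int, z2: int) -> float:
    """Pearson correlation zeta(z1, z2) between two band images."""
    f1 = cube.band_float(z1)
    f2 = cube.band_float(z2)
    return band_image_correlation(f1, f2)


def band_image_correlation(f1: np.ndarray, f2: np.ndarray) -> float:
    """Pearson correlation between two equally shaped band images."""
    if f1.shape != f2.shape:
        raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")
    d1 = f1 - f1.mean()
    d2 = f2 - f2.mean()
    s1 = np.sum(d1 * d1)
    s2 = np.sum(d2 * d2)
    if s1 == 0.0 or s2 == 0.0:
        raise ConstantBandError("spectral correlation undefined for a constant band")
    zeta = float(np.sum(d1 * d2) / math.sqrt(s1 * s2))
    return float(np.clip(zeta, -1.0, 1.0))


def adjacent_spectral_correlations(cube: HyperspectralCube) -> np.ndarray:
    """zeta(z, z+1) for z = 0..c-2; NaN where a band is constant."""
    out = np.empty(cube.bands - 1)
    for z in range(cube.bands - 1):
        try:
            out[z] = spectral_correlation(cube, z, z + 1)
        except ConstantBandError:
            out[z] = np.nan
    return out


def correlation_curves(
    cube: HyperspectralCube, band: int, lag_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row and column autocorrelation curves eta(d,0) and eta(0,d), d=1..lag_max."""
    img = cube.band_float(band)
    lag_max = min(lag_max, cube.rows - 1, cube.cols - 1)
    row = np.array([_autocorr_image(img, d, 0) for d in range(1, lag_max + 1)])
    col = np.array([_autocorr_image(img, 0, d) for d in range(1, lag_max + 1)])
    return row, col


def _default_eval_bands(cube: HyperspectralCube) -> list[int]:
    if cube.wavelengths is not None:
        return sorted(
            {
                int(np.argmin(np.abs(cube.wavelengths - w)))
                for w in DEFAULT_EVAL_WAVELENGTHS
            }
        )
    c = cube.bands
    return sorted({0, c // 2, c - 1})


@dataclass
class EvaluationReport:
    """Aggregated original-vs-reconstruction quality report."""

    psnr_db: float | None
    identical: bool
    per_band_psnr_db: list
    eval_bands: list
    lag_max: int
    row_corr: dict        # band -> curve (original/recon pairs)
    col_corr: dict
    spectral_corr: dict   # adjacent-band zeta curves for original and recon
    spectral_profiles: dict  # mean spectrum per cube
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def _clean(x):
            if isinstance(x, dict):
                return {str(k): _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            if isinstance(x, np.ndarray):
                return _clean(x.tolist())
            if isinstance(x, (np.floating, float)):
                v = float(x)
                return None if not math.isfinite(v) else v
            if isinstance(x, np.integer):
                return int(x)
            return x

        text = json.dumps(_clean(self.__dict__), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        raw = json.loads(text)
        return cls(**raw)


def evaluate(
    orig: HyperspectralCube,
    recon: HyperspectralCube,
    eval_bands: list[int] | None = None,
    lag_max: int = 32,
) -> EvaluationReport:
    """Full spatial + spectral evaluation of a reconstruction.

    Aggregate PSNR uses the 3-D MSE over all voxels (not the mean of
    per-band PSNRs); per-band PSNR, row/column autocorrelation curves for
    the selected bands, adjacent-band spectral-correlation curves, and mean
    spectral profiles are reported alongside.
    """
    _check_same_shape(orig, recon)
    if eval_bands is None:
        eval_bands = _default_eval_bands(orig)

    total = psnr(orig, recon)
    identical = math.isinf(total)
    band_psnr = per_band_psnr(orig, recon)

    row_corr: dict = {}
    col_corr: dict = {}
    for z in eval_bands:
        ro, co = correlation_curves(orig, z, lag_max)
        rr, cr = correlation_curves(recon, z, lag_max)
        row_corr[z] = {"original": ro, "reconstructed": rr}
        col_corr[z] = {"original": co, "reconstructed": cr}

    spectral_corr = {
        "original": adjacent_spectral_correlations(orig),
        "reconstructed": adjacent_spectral_correlations(recon),
    }
    profiles = {
        "original": orig.data.mean(axis=(0, 1)),
        "reconstructed": recon.data.mean(axis=(0, 1)),
    }
    if orig.wavelengths is not None:
        profiles["wavelengths_nm"] = orig.wavelengths

    return EvaluationReport(
        psnr_db=None if identical else total,
        identical=identical,
        per_band_psnr_db=band_psnr,
        eval_bands=list(eval_bands),
        lag_max=lag_max,
        row_corr=row_corr,
        col_corr=col_corr,
        spectral_corr=spectral_corr,
        spectral_profiles=profiles,
    )
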