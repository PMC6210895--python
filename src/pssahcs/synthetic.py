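"""Synthetic hyperspectral cubes with the structure the codec exploits.

A generated cube emulates a visible/NIR leaf scene: per spectral group one
spatially autocorrelated latent "scene" (a separable AR(1) Gaussian field),
each band an affine transform of its group's scene mapped into the central
part of the DN range, and designated "absorption" bands carrying elevated
additive Gaussian noise (the atmospheric-absorption bands near the spectrum
ends of real visible/NIR acquisitions). The generator returns both the
noisy cube and the noise-free ground truth, plus the planted grouping, so
band clustering, key-band selection, prediction and denoising can all be
scored against known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .cube import HyperspectralCube
from .grouping import SpectralGrouping

__all__ = ["SynthSpec", "GroundTruth", "ar1_field", "generate_cube", "tea_like_spec"]


def ar1_field(a: int, b: int, rho: float, seed: int | np.random.Generator) -> np.ndarray:
    """Separable AR(1) Gaussian field of shape (a, b), unit marginal variance.

    The expected lag-(1,0) and lag-(0,1) autocorrelations both equal
    ``rho``. A single white-noise field is colored along each axis by the
    exact stationary AR(1) map (x_0 = e_0, x_t = rho x_{t-1} +
    sqrt(1 - rho^2) e_t), whose covariance is exactly the AR(1) correlation
    matrix, so the result has the exact separable covariance with no
    warm-up samples.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = np.sqrt(1.0 - rho * rho)

    def _color(e: np.ndarray, axis: int) -> np.ndarray:
        e = e.copy()
        first = (0,) if axis == 0 else (slice(None), 0)
        e[first] /= scale  # so the filtered first sample is e_0 itself
        return scipy.signal.lfilter([scale], [1.0, -rho], e, axis=axis)

    e = rng.standard_normal((a, b))
    if rho == 0.0:
        return e
    return _color(_color(e, axis=0), axis=1)


@dataclass
class SynthSpec:
    """Recipe for one synthetic cube.

    ``groups`` lists, per spectral group, the half-open band range and the
    per-band affine coefficients mapping the group's latent scene into DN:
    band z = slope[z] * scene_dn + intercept[z]. ``noisy_bands`` lists
    (band index, additive noise std in DN).
    """

    a: int
    b: int
    c: int
    n_bits: int = 12
    rho: float = 0.97
    groups: list = field(default_factory=list)  # [(start, stop, slopes, intercepts)]
    noisy_bands: list = field(default_factory=list)  # [(band, std_dn)]
    background: float = 0.04  # relative texture amplitude outside the leaf
    seed: int = 0

    def __post_init__(self):
        covered = []
        for start, stop, slopes, intercepts in self.groups:
            if len(slopes) != stop - start or len(intercepts) != stop - start:
                raise ValueError("one slope/intercept per band in the range required")
            covered.extend(range(start, stop))
        if sorted(covered) != list(range(self.c)):
            raise ValueError("group ranges must partition 0..c-1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if any(std < 0 for _, std in self.noisy_bands):
            raise ValueError("noise std must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure accompanying a generated cube."""

    grouping: SpectralGrouping
    clean_cube: HyperspectralCube          # noise-free, rounded to DN
    clean_float: np.ndarray                # noise-free, before rounding
    scenes: list                            # latent DN-scaled scene per group
    slopes: np.ndarray                      # per band, wrt the group scene
    intercepts: np.ndarray
    noisy_bands: list

    def planted_affine(self, band: int, ref_band: int) -> tuple[float, float]:
        """The exact (m, n) predicting ``band`` from ``ref_band`` in the
        clean cube (both must share a group)."""
        if self.grouping.group_of(band) != self.grouping.group_of(ref_band):
            raise ValueError("bands are in different planted groups")
        m = self.slopes[band] / self.slopes[ref_band]
        n = self.intercepts[band] - m * self.intercepts[ref_band]
        return float(m), float(n)


def _leaf_envelope(a: int, b: int, background: float) -> np.ndarray:
    """Smooth amplitude envelope: full texture inside an inscribed ellipse
    (the leaf), attenuated to ``background`` outside it.

    Emulates a leaf imaged against a homogeneous stage background; the
    near-flat background blocks are what a local-statistics noise estimator
    keys on in real acquisitions.
    """
    y, x = np.meshgrid(np.linspace(-1, 1, b), np.linspace(-1, 1, a))
    r = np.sqrt((x / 0.85) ** 2 + (y / 0.85) ** 2)
    # raised-cosine transition over r in [0.9, 1.1] of the ellipse radius
    t = np.clip((r - 0.9) / 0.2, 0.0, 1.0)
    return background + (1.0 - background) * 0.5 * (1 + np.cos(np.pi * t))


def generate_cube(spec: SynthSpec) -> tuple[HyperspectralCube, GroundTruth]:
    """Generate a cube per ``spec``; returns (noisy cube, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    dn_max = (1 << spec.n_bits) - 1

    # Zero-mean latent scene per group: an AR(1) texture shaped by the
    # shared leaf envelope, scaled so slope-1 bands with a mid-range
    # intercept stay in the central 80% of the DN range (~4 sigma margin);
    # band brightness comes from the intercept, not the scene, so added
    # noise and affine transforms rarely clip.
    envelope = _leaf_envelope(spec.a, spec.b, spec.background)
    scenes = []
    for _ in spec.groups:
        s = ar1_field(spec.a, spec.b, spec.rho, rng)
        s = (s - s.mean()) / s.std()
        scenes.append(0.8 * dn_max / 8.0 * s * envelope)

    slopes = np.empty(spec.c)
    intercepts = np.empty(spec.c)
    clean = np.empty((spec.a, spec.b, spec.c))
    groups = []
    for gi, (start, stop, g_slopes, g_inter) in enumerate(spec.groups):
        groups.append(list(range(start, stop)))
        for off, z in enumerate(range(start, stop)):
            slopes[z] = g_slopes[off]
            intercepts[z] = g_inter[off]
            clean[:, :, z] = g_slopes[off] * scenes[gi] + g_inter[off]

    noisy = clean.copy()
    noise_std = dict(spec.noisy_bands)
    for z, std in noise_std.items():
        if std > 0:
            noisy[:, :, z] += rng.normal(0.0, std, size=(spec.a, spec.b))

    def _to_dn(arr: np.ndarray) -> np.ndarray:
        return np.clip(np.round(arr), 0, dn_max).astype(np.uint16)

    wavelengths = np.linspace(380.0, 1030.0, spec.c)
    cube = HyperspectralCube(
        data=_to_dn(noisy), bit_depth=spec.n_bits, wavelengths=wavelengths
    )
    clean_cube = HyperspectralCube(
        data=_to_dn(clean), bit_depth=spec.n_bits, wavelengths=wavelengths
    )
    grouping = SpectralGrouping(
        groups=groups, key_bands=[None] * len(groups), k=len(groups), seed=spec.seed
    )
    truth = GroundTruth(
        grouping=grouping,
        clean_cube=clean_cube,
        clean_float=clean,
        scenes=scenes,
        slopes=slopes,
        intercepts=intercepts,
        noisy_bands=list(spec.noisy_bands),
    )
    return cube, truth


def tea_like_spec(
    a: int = 128,
    b: int = 256,
    c: int = 40,
    seed: int = 0,
    rho: float = 0.97,
    noise_std: float = 60.0,
    n_groups: int = 3,
) -> SynthSpec:
    """The default leaf-scene preset: 128 x 256 x 40, 12-bit, rho = 0.97,
    three contiguous spectral groups, and noisy bands (std 60 DN) at both
    spectral ends, mimicking visible/NIR atmospheric-absorption bands.

    Within-group slopes vary smoothly by a few percent around 1 (the
    band-to-band gain drift of one spectral window) so adjacent bands are
    highly correlated while still distinct; each group sits at its own
    brightness level, with a mild smooth per-band intercept drift. The
    small gain spread also keeps sub-block texture differences between the
    bands of a group well below the designated noise, so the LMLSD noise
    ordering the generator promises (every noisy band scores below every
    clean band of its group) holds by construction.
    """
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, c, n_groups + 1).astype(int)
    levels = np.linspace(0.38, 0.62, n_groups) * 4095   # per-group brightness
    groups = []
    for gi in range(n_groups):
        start, stop = int(edges[gi]), int(edges[gi + 1])
        n = stop - start
        slopes = 0.98 + 0.04 * rng.random(n)            # in [0.98, 1.02]
        slopes = np.sort(slopes)                        # smooth within group
        intercepts = levels[gi] + np.sort(rng.normal(0.0, 20.0, n))
        groups.append((start, stop, slopes.tolist(), intercepts.tolist()))
    noisy = [(0, noise_std), (1, noise_std), (c - 2, noise_std), (c - 1, noise_std)]
    return SynthSpec(
        a=a, b=b, c=c, n_bits=12, rho=rho, groups=groups,
        noisy_bands=noisy, seed=seed,
    )
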