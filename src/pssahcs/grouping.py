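"""Adaptive spectral grouping and key-band selection.

Bands of a hyperspectral cube are partitioned into groups of high mutual
spectral correlation by k-means over vectorized band images (Euclidean
distance between full band images). Within each group the least-noisy band
is chosen as the *key band* by the local-means / local-standard-deviations
(LMLSD) criterion: tile the band into sub-blocks, histogram the sub-block
standard deviations, and score the band by

    R = 20 * log10(M_mean / D_mean)

where M_mean and D_mean are the mean sub-block gray level and standard
deviation over the modal histogram interval. Homogeneous sub-blocks
dominate the modal interval, so D_mean estimates the band's noise floor and
a larger R means a cleaner band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blocking import BlockPlan
from .cube import HyperspectralCube
from .errors import ConstantBandError
from .evaluation import adjacent_spectral_correlations

__all__ = [
    "SpectralGrouping",
    "LmlsdScore",
    "band_distance",
    "group_bands_kmeans",
    "lmlsd_score",
    "select_key_bands",
]


@dataclass
class SpectralGrouping:
    """Partition of band indices into groups, each with an optional key band."""

    groups: list[list[int]]
    key_bands: list[int | None]
    k: int
    seed: int

    def __post_init__(self):
        if len(self.key_bands) != len(self.groups):
            raise ValueError("one key-band slot per group required")
        seen = sorted(z for g in self.groups for z in g)
        if seen != list(range(len(seen))):
            raise ValueError("groups must partition the band indices 0..c-1")
        for kb, g in zip(self.key_bands, self.groups):
            if kb is not None and kb not in g:
                raise ValueError(f"key band {kb} not a member of its group")

    @property
    def n_bands(self) -> int:
        return sum(len(g) for g in self.groups)

    def labels(self) -> np.ndarray:
        lab = np.empty(self.n_bands, dtype=np.int32)
        for gi, g in enumerate(self.groups):
            lab[g] = gi
        return lab

    def group_of(self, band: int) -> int:
        return int(self.labels()[band])

    def key_of(self, band: int) -> int | None:
        return self.key_bands[self.group_of(band)]


def band_distance(cube: HyperspectralCube, zi: int, zc_image: np.ndarray) -> float:
    """Euclidean distance between band ``zi`` and a centroid image.

    The square root of the sum of squared per-pixel differences — the
    distance used by the band k-means.
    """
    f = cube.band_float(zi)
    zc_image = np.asarray(zc_image, dtype=np.float64)
    if f.shape != zc_image.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {zc_image.shape}")
    d = f - zc_image
    return float(np.sqrt(np.sum(d * d)))


# ---------------------------------------------------------------------------
# k-means over vectorized band images
# ---------------------------------------------------------------------------

def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids proportionally to squared
    distance from the nearest already chosen one."""
    c = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    first = int(rng.integers(c))
    centroids[0] = X[first]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0.0:
            idx = int(rng.integers(c))
        else:
            idx = int(rng.choice(c, p=d2 / total))
        centroids[j] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd iterations; converges when assignments stop changing.

    Ties in assignment break toward the lower centroid index (np.argmin).
    An empty cluster is re-seeded from the band farthest from its assigned
    centroid.
    """
    c = X.shape[0]
    labels = np.full(c, -1, dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        for j in range(centroids.shape[0]):
            if not np.any(new_labels == j):
                far = int(np.argmax(d2[np.arange(c), new_labels]))
                centroids[j] = X[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(centroids.shape[0]):
            members = X[labels == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
    return labels, centroids


def _smooth_contiguous(labels: np.ndarray, max_sweeps: int = 1000) -> np.ndarray:
    """Width-3 sliding-window majority relabeling until stable.

    With three elements a strict majority exists unless all three differ, in
    which case the centre label is kept. Endpoints keep their label unless
    their single neighbour pair agrees against them.
    """
    lab = labels.copy()
    c = len(lab)
    for _ in range(max_sweeps):
        new = lab.copy()
        for i in range(c):
            window = lab[max(0, i - 1) : i + 2]
            vals, counts = np.unique(window, return_counts=True)
            best = counts.max()
            if best > len(window) - best:
                new[i] = vals[np.argmax(counts)]
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


def _runs(labels: np.ndarray) -> list[list[int]]:
    """Maximal runs of constant label, in band order."""
    groups: list[list[int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            groups.append(list(range(start, i)))
            start = i
    return groups


def _auto_boundaries(cube: HyperspectralCube, threshold: float) -> list[list[int]]:
    """Contiguous runs split where adjacent-band correlation drops below
    ``threshold`` — the auto-k rule."""
    zeta = adjacent_spectral_correlations(cube)
    cuts = [z for z in range(cube.bands - 1) if not (zeta[z] >= threshold)]
    groups = []
    start = 0
    for cut in cuts:
        groups.append(list(range(start, cut + 1)))
        start = cut + 1
    groups.append(list(range(start, cube.bands)))
    return groups


def group_bands_kmeans(
    cube: HyperspectralCube,
    k: int | str = "auto",
    seed: int = 0,
    contiguity: bool = True,
    adjacent_corr_threshold: float = 0.9,
    max_iter: int = 300,
) -> SpectralGrouping:
    """Partition bands into k groups by k-means over band images.

    With ``k="auto"`` the number of groups is chosen from the adjacent-band
    spectral-correlation curve: every drop of zeta(z, z+1) below
    ``adjacent_corr_threshold`` marks a group boundary, and the resulting
    contiguous runs seed the k-means centroids. With numeric k, k-means++
    seeding from ``seed`` is used. When ``contiguity`` is on (default) the
    final labels are smoothed to contiguous wavelength runs, which is what
    key-band prediction assumes.

    Key bands are left unset; see :func:`select_key_bands`.
    """
    c = cube.bands
    X = cube.data.reshape(-1, c).T.astype(np.float64)  # (c, a*b)
    rng = np.random.default_rng(seed)

    if k == "auto":
        seed_groups = _auto_boundaries(cube, adjacent_corr_threshold)
        k_num = len(seed_groups)
        centroids = np.stack([X[g].mean(axis=0) for g in seed_groups])
    else:
        k_num = int(k)
        if not 1 <= k_num <= c:
            raise ValueError(f"k must be in [1, {c}], got {k_num}")
        if k_num == c:
            return SpectralGrouping(
                groups=[[z] for z in range(c)],
                key_bands=[None] * c,
                k=c,
                seed=seed,
            )
        centroids = _kmeanspp_init(X, k_num, rng)

    labels, _ = _lloyd(X, centroids, max_iter)
    if contiguity:
        labels = _smooth_contiguous(labels)
        groups = _runs(labels)
    else:
        present = [j for j in range(k_num) if np.any(labels == j)]
        groups = [sorted(np.nonzero(labels == j)[0].tolist()) for j in present]

    return SpectralGrouping(
        groups=groups, key_bands=[None] * len(groups), k=len(groups), seed=seed
    )


# ---------------------------------------------------------------------------
# LMLSD noise scoring
# ---------------------------------------------------------------------------

@dataclass
class LmlsdScore:
    """LMLSD noise score of one band under a given sub-block tiling."""

    band: int
    R: float
    modal_interval: tuple[float, float]
    M_mean: float
    D_mean: float
    block_means: np.ndarray = field(repr=False, default=None)
    block_stds: np.ndarray = field(repr=False, default=None)


def lmlsd_score(
    cube: HyperspectralCube,
    band: int,
    block: BlockPlan,
    n_intervals: int = 10,
) -> LmlsdScore:
    """Score band ``band`` by the LMLSD criterion.

    Each sub-block of the tiling contributes its mean gray level and its
    standard deviation (sample form, divisor a*b - 1). The range
    [min std, max std] is split into ``n_intervals`` equal-width intervals;
    the interval holding the most sub-blocks is the modal interval (ties go
    to the lower interval), and R = 20*log10(M_mean / D_mean) over its
    sub-blocks.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    blocks = block.to_blocks(cube.band_float(band))
    means = blocks.mean(axis=(1, 2))
    stds = blocks.std(axis=(1, 2), ddof=1)
    if np.all(stds == 0.0):
        raise ConstantBandError(
            f"band {band}: every sub-block is constant; LMLSD undefined"
        )

    d_lo, d_hi = float(stds.min()), float(stds.max())
    if d_hi == d_lo:
        members = np.ones(len(stds), dtype=bool)
        interval = (d_lo, d_hi)
    else:
        width = (d_hi - d_lo) / n_intervals
        idx = np.minimum(((stds - d_lo) / width).astype(int), n_intervals - 1)
        counts = np.bincount(idx, minlength=n_intervals)
        modal = int(np.argmax(counts))  # argmax ties -> lower interval
        members = idx == modal
        interval = (d_lo + modal * width, d_lo + (modal + 1) * width)

    m_mean = float(means[members].mean())
    d_mean = float(stds[members].mean())
    if d_mean == 0.0:
        r = math.inf
    elif m_mean <= 0.0:
        r = -math.inf
    else:
        r = 20.0 * math.log10(m_mean / d_mean)
    return LmlsdScore(
        band=band,
        R=r,
        modal_interval=interval,
        M_mean=m_mean,
        D_mean=d_mean,
        block_means=means,
        block_stds=stds,
    )


def select_key_bands(
    cube: HyperspectralCube,
    grouping: SpectralGrouping,
    block: BlockPlan,
    n_intervals: int = 10,
) -> SpectralGrouping:
    """Set each group's key band to its highest-R (least noisy) member.

    Singleton groups take their only band; ties in R break toward the
    smaller band index.
    """
    keys: list[int | None] = []
    for g in grouping.groups:
        if len(g) == 1:
            keys.append(g[0])
            continue
        best_band, best_r = None, -math.inf
        for z in g:
            r = lmlsd_score(cube, z, block, n_intervals).R
            if r > best_r:  # strict: ties keep the earlier (smaller) band
                best_band, best_r = z, r
        keys.append(best_band)
    return SpectralGrouping(
        groups=[list(g) for g in grouping.groups],
        key_bands=keys,
        k=grouping.k,
        seed=grouping.seed,
    )
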