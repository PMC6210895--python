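"""End-to-end codec orchestration.

Compression runs: adaptive block-size selection -> spectral grouping ->
LMLSD key-band selection -> per group: compressively sample and
reconstruct the key band, then closed-loop predict each non-key band from
the *reconstructed* key band and compressively sample the residual ->
quantize all measurements -> package. Closed-loop prediction (fitting
against the reconstruction the decoder will actually have) avoids
encoder/decoder drift.

Decompression regenerates the sensing operators from the recorded seeds,
StOMP-reconstructs key bands, then residuals, re-adds predictions, clips
to the DN range, rounds once, and strips the padding.

A blocked-CS baseline (every band its own key band; no grouping or
prediction) is provided for comparisons at the same bit budget.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import cs
from .blocking import BlockPlan, make_plan, select_block_size
from .config import CodecConfig
from .cube import HyperspectralCube
from .errors import ConstantBandError, InfeasibleBudgetError
from .grouping import SpectralGrouping, group_bands_kmeans, select_key_bands
from .package import CompressedPackage
from .prediction import PredictorPair, fit_predictor, predict

__all__ = ["compress", "decompress", "baseline_blocked_cs", "CodecConfig"]


def _measurement_counts(
    cfg: CodecConfig, n_pixels: int, n_bits: int, n_keys: int, n_bands: int
) -> tuple[int, int]:
    """Per-block measurement counts (key band, non-key band) from the rate.

    ``budget_split`` is the key/non-key per-band measurement ratio; the
    counts are scaled so the cube's total measurement budget stays at the
    target rate whatever the split (when every band is a key band the
    split cancels and each band gets exactly the target budget).
    """
    target = cfg.bpp * n_pixels * n_bits / cfg.quant_bits
    n_nonkey = n_bands - n_keys
    base = target * n_bands / (n_keys * cfg.budget_split + n_nonkey)
    m_res = int(round(base))
    m_key = int(round(base * cfg.budget_split))
    if min(m_key, m_res if n_nonkey else m_key) < 1 or round(target) < 1:
        min_rate = cfg.quant_bits / (n_pixels * n_bits)
        raise InfeasibleBudgetError(cfg.bpp, min_rate)
    return min(m_key, n_pixels), min(max(m_res, 1), n_pixels)


def _plan_for(cube: HyperspectralCube, cfg: CodecConfig) -> tuple[BlockPlan, int]:
    """Adaptive plan with the codec's practical block-size clamp applied.

    Returns the clamped plan and the raw (unclamped) selected block size.
    """
    raw = select_block_size(
        cube,
        band_sample=None,
        lag_max=cfg.lag_max,
        lo=cfg.corr_lo,
        hi=cfg.corr_hi,
        fallback_min=cfg.block_min,
    )
    M = int(np.clip(raw.block_size, cfg.block_min, cfg.block_max))
    M = min(M, cube.rows, cube.cols)
    return make_plan(cube.rows, cube.cols, M), raw.block_size


def _quant_dtype(q_bits: int):
    return np.uint16 if q_bits <= 16 else np.uint32


def _sense_band(image_padded: np.ndarray, plan: BlockPlan,
                op: cs.SensingOperator) -> np.ndarray:
    """Measure every block of a padded band image; returns (n_blocks, m)."""
    X = plan.to_blocks(image_padded).reshape(plan.n_blocks, -1)
    return X @ op.phi.T


def _reconstruct_band(Y: np.ndarray, plan: BlockPlan, op: cs.SensingOperator,
                      cfg: CodecConfig) -> np.ndarray:
    """StOMP-reconstruct a padded band image from per-block measurements."""
    M = plan.block_size
    blocks = np.empty((plan.n_blocks, M, M))
    for i in range(plan.n_blocks):
        blocks[i] = cs.reconstruct_block(
            Y[i], op, t=cfg.stomp_t, max_stages=cfg.stomp_max_stages,
            tol=cfg.stomp_tol,
        )
    return plan.from_blocks(blocks)


def compress(cube: HyperspectralCube, cfg: CodecConfig) -> CompressedPackage:
    """Compress a cube into a self-contained package."""
    plan, raw_M = _plan_for(cube, cfg)
    grouping = group_bands_kmeans(
        cube,
        k=cfg.k,
        seed=cfg.kmeans_seed,
        contiguity=cfg.contiguity,
        adjacent_corr_threshold=cfg.adjacent_corr_threshold,
    )
    # key-band noise scoring uses its own fine tiling: local statistics
    # need many small windows, independent of the CS block size
    lmlsd_plan = make_plan(cube.rows, cube.cols, cfg.lmlsd_block_size)
    grouping = select_key_bands(cube, grouping, lmlsd_plan, cfg.lmlsd_intervals)

    N = plan.block_pixels
    m_key, m_res = _measurement_counts(
        cfg, N, cube.bit_depth, len(grouping.groups), cube.bands
    )
    op_key = cs.make_operator(plan.block_size, m_key, cfg.matrix_seed)
    op_res = op_key if m_res == m_key else cs.make_operator(
        plan.block_size, m_res, cfg.matrix_seed
    )

    c = cube.bands
    m_max = max(m_key, m_res)
    meas = np.zeros((c, plan.n_blocks, m_max), dtype=_quant_dtype(cfg.quant_bits))
    meas_counts = np.zeros(c, dtype=np.int32)
    q_lo = np.zeros(c)
    q_hi = np.zeros(c)
    predictors: dict[int, PredictorPair] = {}
    dn_max = float(cube.dn_max)

    def _store(z: int, Y: np.ndarray, m: int) -> np.ndarray:
        """Quantize, record, and return the dequantized measurements the
        decoder will see."""
        codes, lo, hi = cs.quantize(Y, cfg.quant_bits)
        meas[z, :, :m] = codes
        meas_counts[z] = m
        q_lo[z], q_hi[z] = lo, hi
        return cs.dequantize(codes, lo, hi, cfg.quant_bits)

    for gi, group in enumerate(grouping.groups):
        kb = grouping.key_bands[gi]
        key_padded = plan.pad(cube.band_float(kb))
        Y = _sense_band(key_padded, plan, op_key)
        Ydq = _store(kb, Y, m_key)
        recon_key = np.clip(_reconstruct_band(Ydq, plan, op_key, cfg), 0.0, dn_max)

        for z in group:
            if z == kb:
                continue
            target = cube.band_float(z)
            try:
                pair = fit_predictor(plan.unpad(recon_key), target,
                                     band=z, key_band=kb)
            except ConstantBandError:
                pair = PredictorPair(m=0.0, n=float(target.mean()),
                                     band=z, key_band=kb)
            predictors[z] = pair
            resid = plan.pad(target) - predict(recon_key, pair)
            Yr = _sense_band(resid, plan, op_res)
            _store(z, Yr, m_res)

    pkg = CompressedPackage(
        config=dataclasses.replace(cfg),
        block_plan=plan,
        grouping=grouping,
        predictors=predictors,
        measurements=meas,
        meas_counts=meas_counts,
        q_lo=q_lo,
        q_hi=q_hi,
        original_shape=cube.shape,
        bit_depth=cube.bit_depth,
        wavelengths=cube.wavelengths,
        side_info={"selected_block_size": int(raw_M),
                   "m_key": m_key, "m_res": m_res},
    )
    pkg.side_info["measurement_bits"] = pkg.measurement_bits()
    pkg.side_info["side_info_bits"] = pkg.side_info_bits()
    pkg.side_info["realized_bpp"] = pkg.realized_bpp()
    return pkg


def decompress(pkg: CompressedPackage) -> HyperspectralCube:
    """Decode a package back into a cube.

    Uses nothing outside the package: operators are regenerated from the
    recorded seeds, bands are reconstructed group by group, predictions are
    re-added, and values are clipped and rounded once at output.
    """
    cfg = pkg.config
    plan = pkg.block_plan
    a, b, c = pkg.original_shape
    dn_max = float((1 << pkg.bit_depth) - 1)

    ops: dict[int, cs.SensingOperator] = {}

    def _op(m: int) -> cs.SensingOperator:
        if m not in ops:
            ops[m] = cs.make_operator(plan.block_size, m, cfg.matrix_seed)
        return ops[m]

    def _band_measurements(z: int) -> np.ndarray:
        m = int(pkg.meas_counts[z])
        return cs.dequantize(
            pkg.measurements[z, :, :m], pkg.q_lo[z], pkg.q_hi[z], cfg.quant_bits
        )

    out = np.empty((a, b, c), dtype=np.float64)
    for gi, group in enumerate(pkg.grouping.groups):
        kb = pkg.grouping.key_bands[gi]
        Y = _band_measurements(kb)
        recon_key = np.clip(
            _reconstruct_band(Y, plan, _op(int(pkg.meas_counts[kb])), cfg),
            0.0, dn_max,
        )
        out[:, :, kb] = plan.unpad(recon_key)
        for z in group:
            if z == kb:
                continue
            pair = pkg.predictors[z]
            Yr = _band_measurements(z)
            resid = _reconstruct_band(Yr, plan, _op(int(pkg.meas_counts[z])), cfg)
            band = predict(recon_key, pair) + resid
            out[:, :, z] = plan.unpad(np.clip(band, 0.0, dn_max))

    data = np.clip(np.round(out), 0, dn_max).astype(
        np.uint16 if pkg.bit_depth <= 16 else np.uint32
    )
    return HyperspectralCube(
        data=data, bit_depth=pkg.bit_depth, wavelengths=pkg.wavelengths
    )


def baseline_blocked_cs(
    cube: HyperspectralCube, cfg: CodecConfig
) -> tuple[HyperspectralCube, CompressedPackage]:
    """Blocked-CS baseline: every band its own key band, no prediction.

    Uses the same block plan, CS engine and per-band measurement budget as
    the full codec (budget_split forced to 1 so each band receives the
    non-key budget). Returns (reconstructed cube, package).
    """
    base_cfg = dataclasses.replace(cfg, k=cube.bands, budget_split=1.0)
    pkg = compress(cube, base_cfg)
    return decompress(pkg), pkg
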