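"""The ``.pssahcs`` compressed-package container.

A package holds everything a decoder needs and nothing else: the codec
configuration (including every seed), the block plan, the spectral
grouping with key bands, the per-band prediction coefficients, and the
quantized measurement vectors with their per-band quantizer ranges.

On disk a package is a single NumPy ``.npz`` archive (a zip of named
arrays) whose ``meta`` entry is a JSON document; the layout is documented
field-by-field in ``docs/package_format.md``. The format is versioned and
loading verifies the version and the structural invariants.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .blocking import BlockPlan
from .config import CodecConfig
from .errors import PackageFormatError
from .grouping import SpectralGrouping
from .prediction import PredictorPair

__all__ = ["CompressedPackage", "save_package", "load_package", "FORMAT_VERSION"]

FORMAT_VERSION = 1
MAGIC = "pssahcs"


@dataclass
class CompressedPackage:
    """All information needed to decode one cube."""

    config: CodecConfig
    block_plan: BlockPlan
    grouping: SpectralGrouping
    predictors: dict                 # band -> PredictorPair (non-key bands only)
    measurements: np.ndarray         # (c, n_blocks, m_max) quantized codes
    meas_counts: np.ndarray          # (c,) measurements per block for each band
    q_lo: np.ndarray                 # (c,) per-band quantizer minimum
    q_hi: np.ndarray                 # (c,) per-band quantizer maximum
    original_shape: tuple            # (a, b, c)
    bit_depth: int
    wavelengths: np.ndarray | None = None
    side_info: dict = field(default_factory=dict)

    def __post_init__(self):
        a, b, c = self.original_shape
        keys = set(self.grouping.key_bands)
        for z in range(c):
            is_key = z in keys
            has_pred = z in self.predictors
            if is_key == has_pred:
                raise PackageFormatError(
                    f"band {z}: must be either a key band or have exactly one "
                    f"predictor pair"
                )
        if self.measurements.shape[0] != c or self.measurements.shape[1] != (
            self.block_plan.n_blocks
        ):
            raise PackageFormatError(
                "measurement array must hold one vector per (band, block)"
            )

    # -- accounting --------------------------------------------------------

    def measurement_bits(self) -> int:
        """Total stored measurement bits: sum over bands of
        blocks x m_meas x quant_bits (exact accounting)."""
        n_blocks = self.block_plan.n_blocks
        return int(self.meas_counts.sum()) * n_blocks * self.config.quant_bits

    def side_info_bits(self) -> int:
        """Prediction coefficients (2 x 64-bit per non-key band), quantizer
        ranges (2 x 64-bit per band) and the two 64-bit seeds."""
        c = self.original_shape[2]
        return 64 * (2 * len(self.predictors) + 2 * c + 2)

    def realized_bpp(self) -> float:
        """Realized rate in the same normalized units as ``config.bpp``:
        stored measurement bits divided by native cube bits."""
        a, b, c = self.original_shape
        return self.measurement_bits() / (a * b * c * self.bit_depth)

    def bits_per_pixel(self) -> float:
        """Plain stored measurement bits per voxel."""
        a, b, c = self.original_shape
        return self.measurement_bits() / (a * b * c)


def _meta_dict(pkg: CompressedPackage) -> dict:
    return {
        "magic": MAGIC,
        "version": FORMAT_VERSION,
        "config": pkg.config.to_dict(),
        "block": {
            "block_size": pkg.block_plan.block_size,
            "rows": pkg.block_plan.rows,
            "cols": pkg.block_plan.cols,
            "pad_rows": pkg.block_plan.pad_rows,
            "pad_cols": pkg.block_plan.pad_cols,
        },
        "grouping": {
            "groups": [list(map(int, g)) for g in pkg.grouping.groups],
            "key_bands": [int(kb) for kb in pkg.grouping.key_bands],
            "k": pkg.grouping.k,
            "seed": pkg.grouping.seed,
        },
        "predictors": {
            str(z): {"m": p.m, "n": p.n, "key_band": p.key_band}
            for z, p in pkg.predictors.items()
        },
        "original_shape": list(pkg.original_shape),
        "bit_depth": pkg.bit_depth,
        "side_info": pkg.side_info,
    }


def save_package(pkg: CompressedPackage, path) -> None:
    """Write a package to ``path`` as a single ``.pssahcs`` file."""
    meta = json.dumps(_meta_dict(pkg))
    arrays = {
        "meta": np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
        "measurements": pkg.measurements,
        "meas_counts": pkg.meas_counts.astype(np.int32),
        "q_lo": pkg.q_lo.astype(np.float64),
        "q_hi": pkg.q_hi.astype(np.float64),
    }
    if pkg.wavelengths is not None:
        arrays["wavelengths"] = np.asarray(pkg.wavelengths, dtype=np.float64)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_package(path) -> CompressedPackage:
    """Read a ``.pssahcs`` package; verifies magic, version and structure."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, OSError, ValueError, KeyError, io.UnsupportedOperation) as exc:
        raise PackageFormatError(f"cannot read package {path}: {exc}") from exc

    try:
        meta = json.loads(bytes(data["meta"]).decode("utf-8"))
    except (KeyError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise PackageFormatError(f"corrupted package metadata: {exc}") from exc

    if meta.get("magic") != MAGIC:
        raise PackageFormatError("not a pssahcs package (bad magic)")
    if meta.get("version") != FORMAT_VERSION:
        raise PackageFormatError(
            f"package version {meta.get('version')} != supported {FORMAT_VERSION}"
        )

    try:
        cfg = CodecConfig.from_dict(meta["config"])
        blk = meta["block"]
        plan = BlockPlan(
            block_size=blk["block_size"],
            rows=blk["rows"],
            cols=blk["cols"],
            pad_rows=blk["pad_rows"],
            pad_cols=blk["pad_cols"],
        )
        grp = meta["grouping"]
        grouping = SpectralGrouping(
            groups=[list(g) for g in grp["groups"]],
            key_bands=list(grp["key_bands"]),
            k=grp["k"],
            seed=grp["seed"],
        )
        predictors = {
            int(z): PredictorPair(
                m=p["m"], n=p["n"], band=int(z), key_band=p["key_band"]
            )
            for z, p in meta["predictors"].items()
        }
        return CompressedPackage(
            config=cfg,
            block_plan=plan,
            grouping=grouping,
            predictors=predictors,
            measurements=data["measurements"],
            meas_counts=data["meas_counts"],
            q_lo=data["q_lo"],
            q_hi=data["q_hi"],
            original_shape=tuple(meta["original_shape"]),
            bit_depth=meta["bit_depth"],
            wavelengths=data.get("wavelengths"),
            side_info=meta.get("side_info", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, PackageFormatError):
            raise
        raise PackageFormatError(f"malformed package structure: {exc}") from exc
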