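"""Hyperspectral cube container and ENVI header + raw binary I/O.

A cube is a 3-D array of digital numbers (DN) indexed ``(row, col, band)``,
with an optional strictly increasing wavelength axis in nanometres and a
declared bit depth (12 bits for typical visible/NIR pushbroom sensors).
On disk, cubes are stored as a plain-text ENVI header next to a raw binary
file; BSQ is written natively and BIL/BIP are converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError, EnviFormatError

__all__ = ["HyperspectralCube", "read_envi", "write_envi"]

# ENVI numeric "data type" codes for integer samples.
_NP_BY_ENVI = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    12: np.uint16,
    13: np.uint32,
}
_ENVI_BY_NP = {np.dtype(v): k for k, v in _NP_BY_ENVI.items()}


def _dtype_for_bits(n_bits: int) -> np.dtype:
    if n_bits <= 8:
        return np.dtype(np.uint8)
    if n_bits <= 16:
        return np.dtype(np.uint16)
    if n_bits <= 32:
        return np.dtype(np.uint32)
    raise ValueError(f"bit depth {n_bits} not supported (max 32)")


@dataclass
class HyperspectralCube:
    """In-memory hyperspectral cube of integer DN values.

    Parameters
    ----------
    data:
        Array of shape ``(rows, cols, bands)`` with non-negative integer
        values below ``2**bit_depth``.
    bit_depth:
        Bits per pixel sample (default 12).
    wavelengths:
        Optional per-band centre wavelengths in nm, strictly increasing.
    """

    data: np.ndarray
    bit_depth: int = 12
    wavelengths: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got {self.data.ndim}-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("cube data must be an integer array (DN values)")
        if self.data.size == 0:
            raise ValueError("cube must have at least one voxel")
        if not 1 <= self.bit_depth <= 32:
            raise ValueError(f"bit_depth must be in [1, 32], got {self.bit_depth}")
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi > (1 << self.bit_depth) - 1:
            raise ValueError(
                f"DN values [{lo}, {hi}] exceed the {self.bit_depth}-bit range"
            )
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (self.bands,):
                raise ValueError("wavelengths must have one entry per band")
            if not np.all(np.diff(self.wavelengths) > 0):
                raise ValueError("wavelengths must be strictly increasing")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def dn_max(self) -> int:
        """Largest representable DN, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def band(self, z: int) -> np.ndarray:
        """Return band ``z`` as a 2-D array (a view, not a copy)."""
        return self.data[:, :, z]

    def band_float(self, z: int) -> np.ndarray:
        """Return band ``z`` as float64 (for numeric work)."""
        return self.data[:, :, z].astype(np.float64)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HyperspectralCube):
            return NotImplemented
        if self.bit_depth != other.bit_depth:
            return False
        if not np.array_equal(self.data, other.data):
            return False
        if (self.wavelengths is None) != (other.wavelengths is None):
            return False
        if self.wavelengths is not None and not np.allclose(
            self.wavelengths, other.wavelengths
        ):
            return False
        return True


# ---------------------------------------------------------------------------
# ENVI header parsing / writing
# ---------------------------------------------------------------------------

def _parse_header_text(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs; ``{...}`` blocks may span lines."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # Join multi-line {...} blocks before splitting on lines.
    pattern = re.compile(r"^\s*([^={}\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def _parse_list(raw: str) -> list[str]:
    inner = raw.strip()
    if inner.startswith("{") and inner.endswith("}"):
        inner = inner[1:-1]
    return [tok.strip() for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def _raw_path_for(header_path: Path, fields: dict) -> Path:
    # Common conventions: X.hdr next to X.raw / X.img / X.dat / X
    stem = header_path.with_suffix("")
    candidates = [
        stem.with_suffix(".raw"),
        stem.with_suffix(".img"),
        stem.with_suffix(".dat"),
        stem,
    ]
    for cand in candidates:
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(
        f"no raw data file found next to {header_path} "
        f"(tried {[str(c.name) for c in candidates]})"
    )


def read_envi(header_path) -> HyperspectralCube:
    """Read an ENVI header + raw binary cube.

    BSQ is read natively; BIL and BIP layouts are transposed to the internal
    ``(row, col, band)`` order. Only integer sample formats are supported.
    """
    header_path = Path(header_path)
    fields = _parse_header_text(header_path.read_text())

    try:
        samples = int(fields["samples"])  # columns
        lines = int(fields["lines"])      # rows
        bands = int(fields["bands"])
        data_type = int(fields["data type"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc

    if data_type not in _NP_BY_ENVI:
        raise EnviFormatError(
            f"unsupported ENVI data type {data_type} (integer samples only)"
        )
    dtype = np.dtype(_NP_BY_ENVI[data_type])
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", "0"))
    interleave = fields.get("interleave", "bsq").lower()

    raw_path = _raw_path_for(header_path, fields)
    n_samples = samples * lines * bands
    expected = offset + n_samples * dtype.itemsize
    actual = raw_path.stat().st_size
    if actual < expected:
        raise DimensionMismatchError(
            f"{raw_path} holds {actual} bytes but header declares "
            f"{lines}x{samples}x{bands} {dtype.itemsize}-byte samples "
            f"({expected} bytes)"
        )

    flat = np.fromfile(raw_path, dtype=dtype, count=n_samples, offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    data = np.ascontiguousarray(data.astype(dtype.newbyteorder("=")))

    if "bit depth" in fields:
        bit_depth = int(fields["bit depth"])
    else:
        bit_depth = dtype.itemsize * 8

    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array([float(t) for t in _parse_list(fields["wavelength"])])

    return HyperspectralCube(data=data, bit_depth=bit_depth, wavelengths=wavelengths)


def write_envi(cube: HyperspectralCube, header_path) -> None:
    """Write a cube as ENVI header + BSQ raw pair (``X.hdr`` + ``X.raw``).

    ``read_envi(write_envi(cube))`` reproduces the cube bit-exactly; the
    non-standard ``bit depth`` header key preserves sub-word depths (e.g.
    12-bit samples stored in uint16).
    """
    header_path = Path(header_path)
    raw_path = header_path.with_suffix(".raw")
    dtype = _dtype_for_bits(cube.bit_depth)

    bsq = cube.data.astype(dtype.newbyteorder("<")).transpose(2, 0, 1)
    raw_path.parent.mkdir(parents=True, exist_ok=True)
    bsq.tofile(raw_path)

    lines = [
        "ENVI",
        "description = {pssahcs hyperspectral cube}",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_BY_NP[dtype]}",
        "interleave = bsq",
        "byte order = 0",
        f"bit depth = {cube.bit_depth}",
    ]
    if cube.wavelengths is not None:
        wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
        lines.append("wavelength units = Nanometers")
        lines.append(f"wavelength = {{{wl}}}")
    header_path.write_text("\n".join(lines) + "\n")
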