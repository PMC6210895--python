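"""Exception types raised across the codec."""


class PssahcsError(Exception):
    """Base class for all package errors."""


class EnviFormatError(PssahcsError, ValueError):
    """Malformed or unsupported ENVI header/raw pair."""


class DimensionMismatchError(EnviFormatError):
    """Raw file size disagrees with the header's declared dimensions."""


class ConstantBandError(PssahcsError, ValueError):
    """An operation's denominator vanishes because a band (or reference
    image) is constant."""


class PackageFormatError(PssahcsError, ValueError):
    """Corrupted, truncated, or version-incompatible compressed package."""


class InfeasibleBudgetError(PssahcsError, ValueError):
    """Requested rate yields fewer than one measurement per block."""

    def __init__(self, rate: float, min_rate: float):
        self.rate = rate
        self.min_rate = min_rate
        super().__init__(
            f"rate {rate:g} is infeasible: minimum achievable rate with the "
            f"current block size and quantizer depth is {min_rate:g}"
        )
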