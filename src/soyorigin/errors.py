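"""Exception hierarchy shared across the package."""


class SoyOriginError(Exception):
    """Base class for all package-specific errors."""


class InputError(SoyOriginError, ValueError):
    """Malformed or out-of-contract input (wrong call count, bad value range...)."""


class NotSoybeanError(SoyOriginError):
    """Marker 1 (the endogenous soybean control) did not amplify.

    Such a sample cannot be scored at all: the assay's validity gate failed,
    so the profile is rejected rather than silently encoded as 0.
    """

    def __init__(self, sample_id: str = "<unknown>"):
        self.sample_id = sample_id
        super().__init__(
            f"sample {sample_id!r}: endogenous control (marker 1) negative; "
            "not scoreable as soybean"
        )


class FormatError(SoyOriginError, ValueError):
    """A file does not conform to its schema (duplicate values, bad checksums...)."""


class UndefinedMetricError(SoyOriginError, ZeroDivisionError):
    """A performance metric was requested with a zero denominator."""
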