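"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: :class:`ValidationError` -> 2,
:class:`DataFormatError` and I/O problems -> 3.
"""


class RembandError(Exception):
    """Base class for all package errors."""


class ValidationError(RembandError, ValueError):
    """Invalid argument, configuration, or precondition violation."""


class DataFormatError(RembandError):
    """Malformed input file (EDF header, hypnogram dialect, manifest)."""


class UnsupportedRateError(ValidationError):
    """Sampling rate for which no dyadic wavelet band mapping covers 1-30 Hz."""


class DegenerateEpochError(RembandError):
    """Epoch whose signal carries no usable power (excluded, never silent)."""
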