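"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes: config errors -> 2,
data errors -> 3, numeric failures -> 4.
"""


class AdvDefendError(Exception):
    """Base class for all package errors."""


class ConfigError(AdvDefendError):
    """Invalid or unparsable configuration."""


class DataError(AdvDefendError):
    """Missing, malformed, or insufficient input data."""


class ShapeError(AdvDefendError):
    """Tensor shape incompatible with a model or operation."""


class CapabilityError(AdvDefendError):
    """A model handle cannot perform the requested operation.

    Raised e.g. when a pretrained backbone is summary-only (no weights
    available offline) and a forward pass or gradient is requested.
    """


class NumericError(AdvDefendError):
    """Training or evaluation produced non-finite values."""
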