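"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
TrainingError -> 4.
"""


class SttError(Exception):
    """Base class for all package errors."""


class ConfigError(SttError):
    """Invalid configuration value or malformed config file."""


class DataError(SttError):
    """Input data violates a precondition (shape, duration, payload)."""


class MontageError(DataError):
    """Channel names do not match the expected electrode montage."""


class FormatError(DataError):
    """File payload cannot be parsed as numeric EEG data."""


class TrainingError(SttError):
    """Optimization failed (divergent loss, non-finite activations)."""
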