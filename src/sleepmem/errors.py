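"""Exception types shared across the package."""


class SleepMemError(Exception):
    """Base class for package-specific errors."""


class InvalidInputError(SleepMemError, ValueError):
    """Malformed argument: non-stochastic matrix, dimension mismatch, etc."""


class ChannelNotFoundError(SleepMemError, KeyError):
    """A named EEG channel is absent from a recording."""


class DegenerateSignalError(SleepMemError, ValueError):
    """An epoch is constant (zero variance) or has zero in-band power."""


class AlignmentError(SleepMemError, ValueError):
    """Signal too short for the requested epoch/label alignment."""


class UnsupportedResamplingError(SleepMemError, ValueError):
    """Requested upsampling; only downsampling (or identity) is supported."""


class InsufficientDataError(SleepMemError, ValueError):
    """Too few samples/subjects for the requested statistic."""
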