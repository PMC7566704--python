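"""Exception hierarchy shared across the package."""


class BarostateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BarostateError, ValueError):
    """Invalid simulation or run configuration."""


class FormatError(BarostateError, ValueError):
    """A file does not conform to the documented on-disk layout."""


class EmptyInputError(BarostateError, ValueError):
    """An input file or series contains no usable data."""


class InvalidInputError(BarostateError, ValueError):
    """Arguments violate an operation's preconditions."""


class NoBeatsError(BarostateError):
    """No pulsatile cardiac cycles could be detected in a waveform."""


class EmptyWindowsError(BarostateError):
    """No usable analysis window exists in any hour block."""


class InsufficientDataError(BarostateError, ValueError):
    """Too few beats to compute the requested quantity."""


class DegenerateDataError(BarostateError):
    """Data variability is zero; the fit criterion is undefined."""


class PipelineError(BarostateError):
    """A pipeline stage failed; the message names the stage and its input."""
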