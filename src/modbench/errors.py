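"""Exception types raised by the pipeline."""


class ModbenchError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ModbenchError):
    """Invalid run configuration (unknown dialect, bad parameter ranges)."""


class FormatError(ModbenchError):
    """An input file does not match its declared dialect."""


class CoordinateError(ModbenchError):
    """A coordinate falls outside the reference or transcript it refers to."""


class UndefinedStatistic(ModbenchError):
    """A statistic's denominator vanished; the value is undefined, not 0."""
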