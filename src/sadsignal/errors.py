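"""Exception hierarchy for sadsignal."""


class SadSignalError(Exception):
    """Base class for all sadsignal errors."""


class InvalidCellError(SadSignalError):
    """Unit-cell parameters are degenerate or unphysical."""


class UndefinedReflectionError(SadSignalError):
    """A computation was requested for the (0,0,0) reflection."""


class MissingElementError(SadSignalError):
    """No scattering parameters are available for the requested element."""


class InvalidParameterError(SadSignalError):
    """A numeric parameter is outside its physical domain."""


class NoSubstructureError(SadSignalError):
    """An anomalous computation was requested on a model with no substructure."""


class PackingError(SadSignalError):
    """The unit cell cannot hold the requested atoms at the distance cutoff."""


class AmbiguousConfigError(SadSignalError):
    """Mutually exclusive configuration options were set together."""


class EmptyDataError(SadSignalError):
    """No usable reflections remain after filtering."""


class UndefinedMetricError(SadSignalError):
    """A statistic (correlation, signal) is undefined for the given input."""


class FormatError(SadSignalError):
    """An input file does not conform to the documented dialect."""
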