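"""Exception hierarchy for methylthermo."""


class MethylthermoError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MethylthermoError):
    """A count table line could not be parsed; the message names the line."""


class DuplicateRecordError(MethylthermoError):
    """The same (chromosome, position, strand) key appears more than once."""


class EmptyTrackError(MethylthermoError):
    """A divergence track could not be built (no shared sites)."""


class SampleSizeError(MethylthermoError):
    """Too few observations for the requested estimation."""


class DegenerateDataError(MethylthermoError):
    """Input data carry no usable variation (e.g. all values identical)."""


class UnitMismatchError(MethylthermoError):
    """Quantities in incompatible units were combined."""
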