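"""Exception hierarchy for the ojip package."""


class OJIPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OJIPError):
    """Input file does not conform to the documented CSV/TSV dialect."""


class ValidationError(OJIPError):
    """A transient violates its structural invariants (monotone time, range, length)."""


class GridMismatchError(OJIPError):
    """Two transients that must share a time grid do not."""


class DegenerateCurveError(OJIPError):
    """An operation requires variable fluorescence but the curve is flat."""


class OutOfRangeError(OJIPError):
    """A requested time mark lies outside the sampled range."""


class ConfigError(OJIPError):
    """A configuration file or generator configuration is invalid."""
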