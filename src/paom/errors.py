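"""Exception hierarchy for the paom package."""


class PaomError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(PaomError):
    """Matrix dimensions or ID orderings are not conformable."""


class AlignmentError(PaomError):
    """Panels or matrices cannot be aligned (empty intersection, ID mismatch)."""


class ParseError(PaomError):
    """A delimited input file is malformed."""


class ConfigurationError(PaomError):
    """An option value is outside its allowed set or range."""


class NumericalError(PaomError):
    """Non-finite values were produced during optimization."""
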