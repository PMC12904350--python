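"""Exception hierarchy for irtcat.

All irtcat errors derive from :class:`IrtcatError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin so untargeted handling still behaves sensibly.
"""


class IrtcatError(Exception):
    """Base class for all irtcat errors."""


class ParameterError(IrtcatError, ValueError):
    """An item parameter or theta value violates the model's domain."""


class DataError(IrtcatError, ValueError):
    """Response data are malformed, incomplete, or inconsistent with the bank."""


class ConfigurationError(IrtcatError, ValueError):
    """A configuration value (grid, prior, stopping rule, spec) is invalid."""


class NumericalError(IrtcatError, ArithmeticError):
    """A numerical operation produced a degenerate result (e.g. zero posterior mass)."""
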