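"""Exception hierarchy.

All errors derive from :class:`CellMechError` so callers can catch the
package's failures with one clause; each also derives from the closest
builtin (``ValueError`` for bad inputs) so generic handling still works.
"""


class CellMechError(Exception):
    """Base class for all cellmech errors."""


class InvalidParameterError(CellMechError, ValueError):
    """A model parameter violates its physical constraint (e.g. k1 <= 0)."""


class DomainError(CellMechError, ValueError):
    """An input value lies outside the mathematical domain (e.g. t < 0)."""


class DegenerateTransientError(CellMechError, ValueError):
    """The creep transient cannot be resolved (back-extrapolated L(0)
    collapses onto or beyond the plateau)."""


class NoContactError(CellMechError, ValueError):
    """No contact point improves on the all-baseline model for an
    indentation curve."""


class InsufficientDataError(CellMechError, ValueError):
    """Too few samples to identify the model (e.g. < 5 post-contact
    points for a Hertz fit, < 4 samples for a 3-parameter creep fit)."""


class ConfigError(CellMechError, ValueError):
    """Missing or inconsistent instrument / run configuration."""


class TableFormatError(CellMechError, ValueError):
    """A delimited input table fails schema validation; the message names
    file, row and column."""
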