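"""Exception hierarchy shared across the package.

All exceptions derive from :class:`AccelBehaveError` so callers can catch
package failures with a single ``except`` clause; most also subclass
``ValueError`` because they signal invalid input rather than internal faults.
"""


class AccelBehaveError(Exception):
    """Base class for all accelbehave errors."""


class FormatError(AccelBehaveError, ValueError):
    """A file or token stream violates the expected layout (e.g. ragged rows)."""


class ParseError(FormatError):
    """A cell that must be numeric could not be parsed."""


class ShapeError(AccelBehaveError, ValueError):
    """Row width incompatible with the declared number of axes."""


class OrderingError(AccelBehaveError, ValueError):
    """Timestamps of a long-format stream are not monotone non-decreasing."""


class ParameterError(AccelBehaveError, ValueError):
    """An argument is outside its documented domain."""


class AlignmentError(AccelBehaveError, ValueError):
    """Two row-aligned structures have incompatible lengths."""


class NameCollisionError(AccelBehaveError, ValueError):
    """Feature tables being combined share a column name."""


class SchemaError(AccelBehaveError, ValueError):
    """A feature table does not carry exactly the columns a model expects."""


class StratificationError(AccelBehaveError, ValueError):
    """A class is too small to survive a stratified split or k-fold partition."""


class DegenerateTaskError(AccelBehaveError, ValueError):
    """Classification requested on fewer than two behavior classes."""
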