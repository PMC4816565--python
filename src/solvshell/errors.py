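"""Exception hierarchy.

All errors derive from :class:`SolvshellError` so callers can catch the
package's failures with a single except clause; subclasses distinguish
validation problems (bad inputs, bad config) from computation problems.
"""


class SolvshellError(Exception):
    """Base class for all solvshell errors."""


class ValidationError(SolvshellError):
    """Input or configuration rejected before any computation."""


class ComputationError(SolvshellError):
    """Failure while computing an analysis."""


class ParseError(ValidationError):
    """Malformed structure or trajectory text."""


class EmptyInputError(ValidationError):
    """A structure, selection or table with zero entries where >=1 is required."""


class CongruenceError(ValidationError):
    """Trajectory frame incompatible with its parent structure."""


class ClassificationError(ValidationError):
    """Residue names not covered by species rules in strict mode."""


class GeometryError(ComputationError):
    """Degenerate geometry (too few or collinear points)."""


class SelectionError(ValidationError):
    """Empty or invalid atom selection."""


class WindowError(ValidationError):
    """Analysis time window outside the trajectory."""


class PBCError(ValidationError):
    """Request incompatible with the periodic box (e.g. bins beyond L/2)."""


class MassError(ValidationError):
    """Non-positive total mass."""


class OutOfTransitionError(ValidationError):
    """Fluorescence point outside the open (F_N, F_D) interval."""


class InsufficientDataError(ValidationError):
    """Too few points for a fit."""


class FeasibilityError(ValidationError):
    """Requested solvent densities cannot be realised in the box."""


class PackingError(ComputationError):
    """Could not place fixture geometry without clashes."""
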