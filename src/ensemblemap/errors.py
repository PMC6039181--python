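"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`EnsembleMapError`, so callers can catch domain failures without
swallowing programming errors.
"""


class EnsembleMapError(Exception):
    """Base class for all ensemblemap errors."""


class ParseError(EnsembleMapError):
    """A structure file could not be parsed (message names the line)."""


class ValidationError(EnsembleMapError):
    """A domain invariant is violated (e.g. occupancy outside [0, 1])."""


class FormatError(EnsembleMapError):
    """A map file header is inconsistent with its data block."""


class DegenerateMapError(EnsembleMapError):
    """A map with zero variance cannot be sigma-scaled."""


class OutOfBoundsError(EnsembleMapError):
    """A point or atom falls outside the map/box bounds."""


class GridMismatchError(EnsembleMapError):
    """Maps in one computation do not share origin/spacing/shape."""


class InsufficientDataError(EnsembleMapError):
    """Too few datasets for a statistical characterization."""


class NoEventError(EnsembleMapError):
    """The dataset is indistinguishable from background in the region."""


class DegenerateCohortError(EnsembleMapError):
    """Every dataset was flagged as an event; no background remains."""


class DegenerateFitError(EnsembleMapError):
    """An occupancy fit is unidentifiable (e.g. identical conformers)."""


class UndefinedScoreError(EnsembleMapError):
    """A density score over an empty atom set is undefined, not zero."""


class AlignmentError(EnsembleMapError):
    """Residue numbering / atom naming of two models cannot be matched."""


class RepresentationError(EnsembleMapError):
    """A residue needs more alternate conformers than the format allows."""


class NoAcceptableCutoffError(EnsembleMapError):
    """No resolution cutoff inside the table satisfies the criteria."""


class FitFailureError(EnsembleMapError):
    """A nonlinear fit failed to converge or the data are uninformative."""
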