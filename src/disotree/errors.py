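"""Exception hierarchy.

All data-level failures raise a subclass of :class:`DisotreeError` so the
command-line layer can distinguish bad input (exit 1) from usage errors
(exit 2, handled by click).
"""


class DisotreeError(Exception):
    """Base class for all data errors raised by this package."""


class AlignmentShapeError(DisotreeError):
    """Alignment rows have unequal lengths."""


class DuplicateIdError(DisotreeError):
    """The same record id occurs more than once."""


class MissingPositionError(DisotreeError):
    """A per-residue score table skips a position."""


class ScoreRangeError(DisotreeError):
    """A disorder score falls outside [0, 1] or is not finite."""


class ProfileMismatchError(DisotreeError):
    """A disorder profile's length disagrees with the ungapped sequence."""


class UnknownIdError(DisotreeError, KeyError):
    """A referenced protein id is absent from the alignment/profile set."""


class IntervalRangeError(DisotreeError):
    """A residue interval extends beyond the sequence."""


class NewickParseError(DisotreeError):
    """Malformed Newick input."""


class NoOverlapError(DisotreeError):
    """Two proteins share no non-missing alignment column."""


class InsufficientOverlapError(DisotreeError):
    """Fewer than three shared leaves between two trees."""


class DegenerateInputError(DisotreeError):
    """A statistical test received an empty or constant group."""


class StaleCoordinatesError(DisotreeError):
    """A substitution's stated wild-type residue disagrees with the sequence."""


class InconsistentCountsError(DisotreeError):
    """Category counts violate 0 <= associated <= total."""


class UndefinedScoreError(DisotreeError):
    """A region score has no scorable columns."""
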