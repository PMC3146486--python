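"""Exception hierarchy shared by all voxelage modules."""


class VoxelAgeError(Exception):
    """Base class for all voxelage errors."""


class GridMismatch(VoxelAgeError):
    """Volumes do not share an identical shape/affine grid."""


class ParseError(VoxelAgeError):
    """A volume or table file could not be read."""


class MissingSubject(VoxelAgeError):
    """A subject present in the image stack is absent from the cohort table."""


class DuplicateSubject(VoxelAgeError):
    """A subject identifier occurs more than once."""


class EmptyMask(VoxelAgeError):
    """No voxel survives mask construction."""


class DegenerateAges(VoxelAgeError):
    """Age vector has zero variance; the slope is unidentifiable."""


class TooFewSubjects(VoxelAgeError):
    """Not enough subjects to satisfy a fitting precondition."""


class RankDeficient(VoxelAgeError):
    """Design matrix is not of full column rank (or df <= 0)."""


class DegenerateSplit(VoxelAgeError):
    """A split-half fold lacks at least one class."""


class InsufficientMisclassifications(VoxelAgeError):
    """A misclassified-age comparison needs errors in both true groups.

    Raised when at least one true group has no misclassified subject —
    e.g. after a perfect classification. Signals that the comparison
    cannot be made, not that anything went wrong upstream.
    """


class DegenerateTable(VoxelAgeError):
    """A contingency table has a zero row or column margin."""


class ZeroVariance(VoxelAgeError):
    """Both group variances are zero with unequal means; t is infinite."""


class SpecError(VoxelAgeError):
    """A phantom specification violates its invariants."""
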