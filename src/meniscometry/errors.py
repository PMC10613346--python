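"""Exception hierarchy shared across the package.

Every anticipated failure mode gets a distinct, named exception so callers
(and the CLI) can react to specific conditions instead of parsing messages.
"""


class MeniscometryError(Exception):
    """Base class for all package-specific errors."""


class VolumeReadError(MeniscometryError):
    """A volume file could not be read or is not a usable NIfTI image."""


class NonIntegerDataError(VolumeReadError):
    """Voxel data are not integer-valued and cannot be a label map."""


class SingularAffineError(VolumeReadError):
    """The voxel-to-mm affine is singular (not invertible)."""


class LabelAbsentError(MeniscometryError):
    """A requested label id has no voxels in the volume."""


class NonAxisAlignedError(MeniscometryError):
    """The affine is not axis-aligned after orientation normalization."""


class TableFormatError(MeniscometryError):
    """A CSV table is ragged, non-numeric, or otherwise malformed."""


class MissingCellError(TableFormatError):
    """A rating grid has blank cells; carries the offending (rater, subject) pairs."""

    def __init__(self, cells):
        self.cells = list(cells)
        pairs = ", ".join(f"({r}, {s})" for r, s in self.cells)
        super().__init__(f"missing cells at (rater, subject): {pairs}")


class EmptyFootprintError(MeniscometryError):
    """A measurement was requested on an empty footprint or empty region."""


class ShapeCollisionError(MeniscometryError):
    """Two phantom structures overlap where they must not."""


class InfeasibleTruncationError(MeniscometryError):
    """A truncated parameter distribution has (effectively) empty support."""


class IncompleteGridError(MeniscometryError):
    """A rating table has missing entries and cannot enter the ICC ANOVA."""


class DegenerateVarianceError(MeniscometryError):
    """Zero between-subject variance: the ICC is undefined, not a number."""
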