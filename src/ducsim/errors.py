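"""Exception hierarchy for contour simulation failures."""


class DucsimError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(DucsimError):
    """Volume/mask geometry is inconsistent (shape, spacing, alignment)."""


class NoSurfaceError(DucsimError):
    """A slice has no foreground, so no boundary can be traced."""


class SurfaceTooSmallError(DucsimError):
    """A traced slice boundary has fewer than 4 entries and cannot be deformed."""


class DisconnectedSliceError(DucsimError):
    """A slice contains more than one foreground component.

    Carries the offending slice indices in ``slices``.
    """

    def __init__(self, slices, msg=None):
        self.slices = list(slices)
        super().__init__(msg or f"disconnected foreground on slice(s) {self.slices}")


class DegenerateContourError(DucsimError):
    """A contour loop is self-intersecting beyond repair or has no interior."""


class CollapsedContourError(DucsimError):
    """Displacement shrank a slice contour below one voxel of interior area."""


class SmoothedAwayError(DucsimError):
    """Gaussian smoothing plus re-thresholding removed the whole structure."""


class EmptyMaskError(DucsimError):
    """A metric or operation received an all-background mask."""


class OverlappingOrgansError(DucsimError):
    """Phantom organ specifications intersect."""


class SingleClassTrainingError(DucsimError):
    """Logistic filter training data contains only one outcome class."""
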