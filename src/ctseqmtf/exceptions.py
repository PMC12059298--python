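"""Exception hierarchy for the MTF measurement pipeline."""


class CTSeqMTFError(Exception):
    """Base class for all package errors."""


class SeriesReadError(CTSeqMTFError):
    """A DICOM series could not be read or is inconsistent."""


class SegmentationError(CTSeqMTFError):
    """Object segmentation failed (e.g. no pixels above threshold)."""


class EdgeLocalizationError(CTSeqMTFError):
    """The object/air edge could not be located."""


class ROIBoundsError(CTSeqMTFError):
    """The edge ROI would cross the image border."""


class DegenerateLSFError(CTSeqMTFError):
    """The LSF is flat after zeroing; there is no edge to measure."""


class MTFFitError(CTSeqMTFError):
    """The parametric MTF model did not converge."""


class ResolutionBeyondNyquistError(CTSeqMTFError):
    """The MTF never falls below the requested level inside the retained band."""


class MeasurementError(CTSeqMTFError):
    """Sequence-level measurement failed on every slice."""


class PhantomGeometryError(CTSeqMTFError):
    """A synthetic phantom specification violates its geometric invariants."""
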