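"""Exception hierarchy for the volseg package.

Every error raised by the public API derives from :class:`VolsegError`
and carries a short machine-readable ``code`` used by the HTTP layer.
"""


class VolsegError(Exception):
    """Base class for all volseg errors."""

    code = "error"


# --- volume_io -------------------------------------------------------------

class UnsupportedModeError(VolsegError):
    """MRC/CCP4 MODE (or SFF lattice mode) outside the supported set."""

    code = "unsupported mode"


class TruncatedMapError(VolsegError):
    """Map file data block shorter than the header promises."""

    code = "truncated map"


class InvalidHeaderError(VolsegError):
    """Malformed MRC/CCP4 header (non-positive sample counts etc.)."""

    code = "invalid header"


class ValueOverflowError(VolsegError):
    """Values do not fit the requested integer storage mode."""

    code = "value overflow"


class EmptyGridError(VolsegError):
    """An operation received a zero-sized grid."""

    code = "empty grid"


# --- sff_io ----------------------------------------------------------------

class InvalidSffError(VolsegError):
    """Malformed EMDB-SFF container."""

    code = "invalid SFF"


class DanglingLatticeError(InvalidSffError):
    """Segment references a lattice id absent from the lattice list."""

    code = "dangling lattice"


class InvalidSegmentationError(VolsegError):
    """SegmentationSet invariants violated on write."""

    code = "invalid segmentation"


# --- store -----------------------------------------------------------------

class EntryExistsError(VolsegError):
    """Entry already present and overwrite not requested."""

    code = "entry exists"


class NotFoundError(VolsegError):
    """Entry / channel / resource not present in the database."""

    code = "not found"


class CorruptEntryError(VolsegError):
    """Stored metadata and arrays disagree."""

    code = "corrupt entry"


# --- bcif_codec ------------------------------------------------------------

class BcifError(VolsegError):
    code = "invalid bcif"


class InvalidPackingError(BcifError):
    code = "invalid packing"


class FixedPointOverflowError(BcifError):
    code = "fixed-point overflow"


class InvalidQuantizationError(BcifError):
    code = "invalid quantization"


class UnsupportedVersionError(BcifError):
    code = "unsupported version"


# --- query_server ----------------------------------------------------------

class InvalidBudgetError(VolsegError):
    code = "invalid budget"


class EmptyRegionError(VolsegError):
    code = "empty region"


# --- fixtures --------------------------------------------------------------

class PlacementFailedError(VolsegError):
    code = "placement failed"
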