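"""Exception hierarchy.

Every error raised deliberately by the package derives from
:class:`DermDecideError`, so callers (and the CLI) can distinguish
user/input problems from genuine bugs.
"""


class DermDecideError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DermDecideError, ValueError):
    """An argument violates a documented precondition."""


class SegmentationError(DermDecideError):
    """Segmentation failed to produce a usable lesion mask."""


class DegenerateImageError(SegmentationError):
    """The image admits no two-region partition (e.g. constant intensity)."""


class FormatError(DermDecideError, ValueError):
    """A file does not conform to the expected on-disk format."""


class CorruptBundleError(DermDecideError):
    """A model bundle could not be read back."""


class InvalidSpecError(DermDecideError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
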