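"""Exception hierarchy.

Every failure mode that callers are expected to handle has its own class so
pipelines can record per-stage failures without string matching.
"""


class AtlasForgeError(Exception):
    """Base class for all package errors."""


class GridMismatchError(AtlasForgeError):
    """Two volumes that must share shape and spacing do not."""


class DegenerateInputError(AtlasForgeError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero)."""


class ZeroVarianceError(AtlasForgeError):
    """Correlation requested over a domain with zero intensity variance."""


class RegistrationFailureError(AtlasForgeError):
    """Affine optimization could not produce a valid transform."""


class StitchFailureError(AtlasForgeError):
    """No admissible stitching offset with sufficient overlap."""


class MaskFailureError(AtlasForgeError):
    """Brain-mask construction produced an empty binarization."""


class EmptyROIError(AtlasForgeError):
    """A region of interest realized to zero voxels."""


class CardinalityError(AtlasForgeError):
    """Too few inputs for a statistically meaningful average."""


class UnknownLineError(AtlasForgeError, KeyError):
    """A line id is not present in the atlas."""


class PhantomSpecError(AtlasForgeError):
    """A synthetic-data specification is internally inconsistent."""


class ManifestError(AtlasForgeError):
    """A project manifest is invalid or references missing files."""
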