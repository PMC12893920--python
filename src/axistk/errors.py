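"""Exception types raised across the toolkit.

All errors derive from :class:`AxisTkError` so callers can catch the
package's failures with a single except clause.
"""


class AxisTkError(Exception):
    """Base class for all axistk errors."""


class FormatError(AxisTkError):
    """Malformed input file (dimension mismatch, non-integer counts, ...)."""


class ZeroLibraryError(AxisTkError):
    """A unit has zero total counts and cannot be depth-normalized."""


class MissingGeneError(AxisTkError):
    """Requested genes are absent from the dataset."""


class DegenerateSectionError(AxisTkError):
    """A section split produced an empty section."""


class NoSharedFeaturesError(AxisTkError):
    """No shared features remain between two datasets."""


class LandmarkNotFoundError(AxisTkError):
    """A landmark label is absent from the spatial dataset."""


class AmbiguousLandmarkError(AxisTkError):
    """A unit is at zero distance from both landmark sets."""


class InvalidTransformError(AxisTkError):
    """An affine transform has a singular linear part."""


class InvalidAnchorError(AxisTkError):
    """Rescaling anchors are not strictly increasing in both coordinates."""


class InsufficientPanelError(AxisTkError):
    """Reference and query share too few genes for transfer."""


class InvalidKError(AxisTkError):
    """k exceeds the usable reference size."""


class InvalidGroupsError(AxisTkError):
    """Trend-test groups are empty or fewer than two."""


class TooLargeForEnumerationError(AxisTkError):
    """Exact permutation enumeration would exceed the instance-size cap."""


class EmptySignatureError(AxisTkError):
    """No signature gene is present in the dataset."""


class LabelNotFoundError(AxisTkError):
    """A requested categorical label is absent from the metadata."""


class MissingLabelError(AxisTkError):
    """Units required to be labelled carry missing labels."""


class InvalidProfileError(AxisTkError):
    """Neighbourhood profiles are not on the same feature list."""


class InvalidProportionError(AxisTkError):
    """A sampling proportion selects fewer than one unit."""


class ConfigError(AxisTkError):
    """A run configuration failed schema validation."""
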