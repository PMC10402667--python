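"""Exception hierarchy for the GDSA QA pipeline.

Each error class marks a distinct failure mode the callers are expected to
handle differently (unreadable input vs. degenerate analysis region, etc.).
"""


class GdsaError(Exception):
    """Base class for all pipeline errors."""


class EpidReadError(GdsaError):
    """An input file could not be read (unreadable, truncated, wrong kind)."""


class MissingMetadataError(EpidReadError):
    """Required geometry metadata (e.g. pixel spacing) is absent."""


class GeometryMismatchError(GdsaError):
    """Images that must share dimensions / pixel pitch do not."""


class EmptyDeliveryError(GdsaError):
    """A composite with no signal (all-zero) cannot be normalized."""


class DegenerateRoiError(GdsaError):
    """No high-dose low-gradient pixels: the fraction is unanalyzable."""


class NotRigidError(GdsaError):
    """A registration matrix whose 3x3 block is not a proper rotation."""


class NoBodyFoundError(GdsaError):
    """No pixel above the body-surface HU threshold on a CT slice."""
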