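"""Exception types shared across the pipeline."""


class KinetoquantError(Exception):
    """Base class for all package-specific errors."""


class ChannelRoleError(KinetoquantError):
    """A channel-role map references a channel the image does not have,
    or a required role is missing."""


class DegenerateImageError(KinetoquantError):
    """An image (or sample) is constant/blank where structure is required,
    e.g. thresholding a flat field."""


class InsufficientBackgroundError(KinetoquantError):
    """Fewer eligible background pixels exist in the image than the
    requested background-ROI size."""


class RoiOutOfBoundsError(KinetoquantError):
    """A region of interest extends beyond the image."""


class FitError(KinetoquantError):
    """A model fit failed to converge or was given unusable input."""
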