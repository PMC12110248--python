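"""Exception types shared across the pipeline."""


class MeiboscanError(Exception):
    """Base class for all package errors."""


class InvalidMaskError(MeiboscanError):
    """The eyelid mask has no usable foreground (or is otherwise unusable)."""


class DimensionMismatchError(MeiboscanError):
    """Image and mask dimensions differ."""


class InputError(MeiboscanError):
    """An input file is missing, unreadable, or malformed."""


class EmptyResultError(MeiboscanError):
    """The pipeline ran but produced no glands."""


class ProfileTooShortError(MeiboscanError):
    """A gray-value profile is shorter than the smoothing window."""
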