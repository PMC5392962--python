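"""Exception and warning types shared across the package."""


class MammoquadError(Exception):
    """Base class for all package-specific errors."""


class InputError(MammoquadError):
    """Invalid input data (non-finite pixels, malformed parameters)."""


class ParameterError(MammoquadError):
    """A configuration or specification parameter is out of its valid range."""


class SizingError(MammoquadError):
    """A phantom breast does not fit inside the requested image frame."""


class DegenerateInputError(MammoquadError):
    """Input too degenerate for the requested operation (e.g. fewer distinct
    gray values than clusters, or no plausible breast foreground)."""


class LandmarkError(MammoquadError):
    """An anatomic landmark (nipple, chest-wall seed) is inconsistent with the
    image or mask it refers to."""


class ChestWallTraceError(MammoquadError):
    """Gradient tracing of the breast-muscle interface failed."""


class DegenerateInputWarning(UserWarning):
    """Signals a documented fallback on degenerate input (e.g. a breast with a
    single tissue class: no dense pixels are reported)."""
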