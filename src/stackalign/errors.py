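"""Exception hierarchy shared across the package."""


class StackAlignError(Exception):
    """Base class for all stackalign errors."""


class ValidationError(StackAlignError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(StackAlignError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. a
    zero-variance frame offered to phase cross-correlation)."""


class DegenerateFramingError(StackAlignError, ValueError):
    """A framing request produced an empty canvas (minimum mode with no
    common overlap between corrected frames)."""


class CapabilityError(StackAlignError, RuntimeError):
    """An optional backend is unavailable in this installation."""
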