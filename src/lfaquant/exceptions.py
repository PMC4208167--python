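"""Exception and warning types used across the package."""


class LFAQuantError(ValueError):
    """Base class for all package errors."""


class InputError(LFAQuantError):
    """Malformed or inconsistent user input (shapes, lengths, unknown keys)."""


class DesignError(LFAQuantError):
    """A requested experimental design cannot be provided."""


class DegenerateDataError(LFAQuantError):
    """Data admit no meaningful fit (all-zero reference, flat calibration, ...)."""


class ConfoundedInteractionWarning(UserWarning):
    """Interaction cell means computed on a design that confounds two-factor
    interactions across all columns (Plackett-Burman L12): screening evidence
    only, resolve with a dedicated 2x2 follow-up experiment."""
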