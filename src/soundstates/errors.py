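"""Exception types shared across the package."""


class SoundStatesError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SoundStatesError, ValueError):
    """A parameter value violates an operation's precondition."""


class InvalidInputError(SoundStatesError, ValueError):
    """Input data are malformed or inconsistent (geometry, alignment, labels)."""


class UnsupportedStimulusError(SoundStatesError, ValueError):
    """A stimulus category is not handled by the requested operation."""


class UndefinedMetricError(SoundStatesError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero noise estimate)."""


class InsufficientDataError(SoundStatesError, ValueError):
    """Too few samples to run the requested statistical procedure."""
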