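"""Exception types shared across the package."""


class MuscnetError(Exception):
    """Base class for all package-specific errors."""


class InputError(MuscnetError, ValueError):
    """Malformed or out-of-contract input (shape, range, missing value)."""


class MetricUndefinedError(MuscnetError, ValueError):
    """A pairwise correlation value is mathematically undefined.

    Raised e.g. for a zero-variance BOLD vector under Pearson/Spearman/Kendall
    or a zero-norm vector under cosine similarity. Carries optional context
    identifying the offending ROI pair and sliding-window index.
    """

    def __init__(self, message: str, pair: tuple | None = None, window: int | None = None):
        super().__init__(message)
        self.pair = pair
        self.window = window


class ManifestError(InputError):
    """Cohort manifest is malformed or references unreadable subject files."""
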