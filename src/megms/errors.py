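"""Exception hierarchy for the microstate pipeline.

All errors derive from :class:`MegmsError` so callers can catch the package's
failures with a single ``except`` clause; argument-contract violations also
derive from :class:`ValueError`.
"""


class MegmsError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MegmsError, ValueError):
    """An argument violates an operation's precondition."""


class GenerationError(MegmsError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class EmptyResultError(MegmsError, RuntimeError):
    """An operation produced no usable output (e.g. every epoch rejected)."""


class UndefinedSimilarityError(MegmsError, ValueError):
    """Spatial similarity requested for a zero-norm topography."""


class UndefinedGevError(MegmsError, ValueError):
    """Global explained variance undefined (zero total field power)."""


class SelectionError(MegmsError, RuntimeError):
    """Cluster-number selection failed (no valid criterion curve)."""
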