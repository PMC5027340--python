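"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: usage/parameter problems -> 2,
file format problems -> 3, analysis failures (e.g. no valid triangles) -> 4.
"""


class EpimapError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EpimapError, ValueError):
    """A function was called with out-of-contract parameters."""


class FormatError(EpimapError):
    """A file could not be parsed or is internally inconsistent."""


class AnalysisError(EpimapError):
    """An analysis stage could not produce a result."""


class NoEstimateError(AnalysisError):
    """No valid triangles remain, so no velocity summary can be formed."""


class EmptyResultError(AnalysisError):
    """An operation produced no usable output (e.g. no channel has a valid neighbor)."""


class UndefinedIndexError(AnalysisError):
    """The heterogeneity index is undefined (median delay is zero)."""


class EmptyMapWarning(UserWarning):
    """Every channel of a map came out invalid; reported, not silent."""
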