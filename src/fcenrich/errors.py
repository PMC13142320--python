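"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`FcEnrichError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class FcEnrichError(Exception):
    """Base class for all fcenrich errors."""


class FormatError(FcEnrichError):
    """A file or table does not conform to the expected dialect."""


class DegenerateMapError(FcEnrichError):
    """An atlas (or residual map) is constant and cannot be ranked."""


class InsufficientRegionsError(FcEnrichError):
    """A percentile threshold leaves fewer than two regions (no edges)."""


class GridError(FcEnrichError):
    """A threshold grid is incompatible with the data or a requested bound."""


class DegenerateNullError(FcEnrichError):
    """A null distribution has zero spread (MAD = 0) and admits no z-score."""


class ConfigError(FcEnrichError):
    """A CLI configuration file is invalid."""
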