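"""Exception hierarchy.

All input-level failures derive from :class:`WagepError` so the CLI can map
them to exit code 2 uniformly.
"""


class WagepError(Exception):
    """Base class for all user-facing errors."""


class ParseError(WagepError):
    """Malformed expression or annotation file; names the offending row/column."""


class ConfigError(WagepError):
    """Invalid configuration value (grid size, window width, scenario, ...)."""


class DegenerateGeneError(WagepError):
    """All pooled values for a gene are identical; no grid can be built."""


class InsufficientSamplesError(WagepError):
    """Fewer usable values than the minimum class size."""


class InsufficientClassesError(WagepError):
    """Fewer than two classes available for a gene."""


class EmptyModelError(WagepError):
    """No gene has at least two eligible classes."""


class NoOverlapError(WagepError):
    """Query shares no usable gene with the reference model."""


class TaxonomyError(WagepError):
    """A class label required for category evaluation is absent from the taxonomy."""


class EmptySelectionError(WagepError):
    """No gene passes the weight threshold for the requested class."""
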