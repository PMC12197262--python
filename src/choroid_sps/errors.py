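"""Exception hierarchy for the SpS pipeline.

Every error raised deliberately by this package derives from :class:`SpsError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class SpsError(Exception):
    """Base class for all errors raised by choroid_sps."""


class FormatError(SpsError):
    """An input file has an unsupported or malformed format."""


class ParameterError(SpsError):
    """A configuration or operation parameter is out of its valid range."""


class SelectionError(SpsError):
    """A superpixel selection refers to labels that do not exist."""


class UndefinedMetricError(SpsError):
    """A metric is undefined for the given input (e.g. COID of an empty mask)."""


class DegenerateDataError(SpsError):
    """A statistic is undefined for degenerate data (zero variance, constant matrix)."""
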