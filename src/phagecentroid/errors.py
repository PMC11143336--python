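"""Exception hierarchy for growth-curve ingestion and analysis."""


class GrowthDataError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GrowthDataError):
    """The input table does not have the expected columns or layout."""


class ParseError(GrowthDataError):
    """A cell could not be parsed, or a structural invariant (e.g. unique
    (sample, time) pairs) is violated; the message names the offending row."""


class AlignmentError(GrowthDataError):
    """Two curves do not share a usable common time grid."""


class DegenerateStripError(GrowthDataError):
    """A strip with zero height at both ends has no defined centroid."""


class DegenerateControlError(GrowthDataError):
    """The control curve has zero area or a zero centroid coordinate product,
    so index values against it are undefined."""


class NotEstimableError(GrowthDataError):
    """A quantity (e.g. maximum specific growth rate) cannot be estimated
    from the available points."""
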